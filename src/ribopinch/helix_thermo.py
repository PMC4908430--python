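"""Nearest-neighbor thermodynamics and information content of the P1.2 helix.

The stability of the peripheral P1.2 helix is scored with the additive
nearest-neighbor model: duplex initiation, one stacking term per
adjacent base-pair step, a terminal penalty for each A-U or G-U helix
end, and (optionally) a hairpin-loop penalty when the helix is capped.
A bundled Turner-2004-style dG37 table drives the calculation and can be
swapped for any table with the same CSV layout.  Only contiguous helices
(Watson-Crick and G.U wobble pairs) are accepted: the P1.2 variant
series consists of perfect duplexes, so internal loops and bulges are
rejected rather than approximated.

Information content uses the 2-bits-per-base-pair convention of
molecular information theory: specifying one of 4 bases at a paired
position costs 2 bits, so an n-bp helix carries 2n bits.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .errors import ParameterTableError, ValidationError

__all__ = [
    "HelixDuplex",
    "NNParamTable",
    "helix_dG37",
    "info_bits",
    "parse_construct_fasta",
    "load_default_params",
]

logger = logging.getLogger(__name__)

_VALID_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
_AU_GU_PAIRS = {("A", "U"), ("U", "A"), ("G", "U"), ("U", "G")}
_RNA_ALPHABET = set("ACGU")


def _normalize_rna(seq: str, label: str = "") -> str:
    seq = seq.strip().upper().replace(" ", "")
    if "T" in seq:
        logger.warning("sequence %s contains T; normalizing T->U", label or seq)
        seq = seq.replace("T", "U")
    bad = set(seq) - _RNA_ALPHABET
    if bad:
        raise ValidationError(
            f"non-RNA characters {sorted(bad)} in sequence {label or seq!r}"
        )
    return seq


@dataclass(frozen=True)
class HelixDuplex:
    """A contiguous RNA helix given as its two strands, each 5'->3'.

    Antiparallel registration: position i of ``strand5`` pairs with
    position (n-1-i) of ``strand3``.  Every aligned position must form a
    Watson-Crick or G.U pair.  ``closing_loop`` is the loop length in nt
    when the helix is capped by a hairpin.
    """

    strand5: str
    strand3: str
    construct_id: str = ""
    closing_loop: int | None = None

    def __post_init__(self):
        s5 = _normalize_rna(self.strand5, f"{self.construct_id}/5'")
        s3 = _normalize_rna(self.strand3, f"{self.construct_id}/3'")
        object.__setattr__(self, "strand5", s5)
        object.__setattr__(self, "strand3", s3)
        if len(s5) != len(s3):
            raise ValidationError(
                f"{self.construct_id or 'duplex'}: strand lengths differ "
                f"({len(s5)} vs {len(s3)})"
            )
        if len(s5) == 0:
            raise ValidationError("empty duplex")
        for i, pair in enumerate(self.pairs):
            if pair not in _VALID_PAIRS:
                raise ValidationError(
                    f"{self.construct_id or 'duplex'}: position {i} "
                    f"{pair[0]}-{pair[1]} is not a Watson-Crick or G.U pair"
                )
        if self.closing_loop is not None and self.closing_loop < 3:
            raise ValidationError("hairpin loops shorter than 3 nt are not allowed")

    @property
    def n_bp(self) -> int:
        return len(self.strand5)

    @property
    def pairs(self) -> list:
        """Base pairs from the 5' end of ``strand5``."""
        return [
            (self.strand5[i], self.strand3[len(self.strand3) - 1 - i])
            for i in range(len(self.strand5))
        ]

    def flipped(self) -> "HelixDuplex":
        """Same physical duplex with the strand roles exchanged."""
        return HelixDuplex(
            strand5=self.strand3,
            strand3=self.strand5,
            construct_id=self.construct_id,
            closing_loop=self.closing_loop,
        )


def _flip_step(key: str) -> str:
    top, bottom = key.split("/")
    return f"{bottom}/{top}"


class NNParamTable:
    """Nearest-neighbor dG37 parameter table (kcal/mol).

    Stack keys use ``top(5'->3')/bottom(5'->3')`` notation, e.g. ``AA/UU``
    is 5'-AA-3' paired with 3'-UU-5'.  The table must contain every
    WC/G.U-compatible step and be symmetric under strand flip
    (``XY/wz`` == ``wz/XY``).
    """

    def __init__(
        self,
        stack_dG37: dict,
        init_dG37: float,
        terminal_AU_penalty: float,
        hairpin_loop_dG37: dict | None = None,
        provenance: str = "unspecified",
    ):
        self.stack_dG37 = dict(stack_dG37)
        self.init_dG37 = float(init_dG37)
        self.terminal_AU_penalty = float(terminal_AU_penalty)
        self.hairpin_loop_dG37 = dict(hairpin_loop_dG37 or {})
        self.provenance = provenance
        self._validate()

    def _validate(self) -> None:
        import itertools

        expected = set()
        for X, Y, w, z in itertools.product("ACGU", repeat=4):
            if (X, z) in _VALID_PAIRS and (Y, w) in _VALID_PAIRS:
                expected.add(f"{X}{Y}/{w}{z}")
        missing = expected - set(self.stack_dG37)
        if missing:
            raise ParameterTableError(
                f"stack table missing {len(missing)} steps, e.g. "
                f"{sorted(missing)[:4]}"
            )
        for key, val in self.stack_dG37.items():
            mirror = _flip_step(key)
            if abs(val - self.stack_dG37.get(mirror, float("nan"))) > 1e-9:
                raise ParameterTableError(
                    f"strand-flip asymmetry: {key}={val} vs "
                    f"{mirror}={self.stack_dG37.get(mirror)}"
                )

    @classmethod
    def from_csv(cls, path) -> "NNParamTable":
        stacks, loops = {}, {}
        init = term = None
        provenance = []
        with open(path, newline="") as fh:
            lines = fh.readlines()
        data_lines = []
        for line in lines:
            if line.startswith("#"):
                provenance.append(line.lstrip("# ").strip())
            elif line.strip():
                data_lines.append(line)
        reader = csv.DictReader(data_lines)
        for row in reader:
            kind, key, val = row["kind"], row["key"], float(row["dG37_kcal"])
            if kind == "stack":
                stacks[key] = val
            elif kind == "init":
                init = val
            elif kind == "terminal_au":
                term = val
            elif kind == "hairpin_loop":
                loops[int(key)] = val
            else:
                raise ParameterTableError(f"unknown row kind {kind!r}")
        if init is None or term is None:
            raise ParameterTableError("table must define init and terminal_au rows")
        return cls(stacks, init, term, loops, provenance=" ".join(provenance))

    def stack(self, pair_outer, pair_inner) -> float:
        """Stack energy for adjacent pairs (outer is 5' on the top strand)."""
        key = f"{pair_outer[0]}{pair_inner[0]}/{pair_inner[1]}{pair_outer[1]}"
        try:
            return self.stack_dG37[key]
        except KeyError:
            raise ParameterTableError(f"no stack entry for step {key}") from None

    def loop_penalty(self, length: int) -> float:
        if length in self.hairpin_loop_dG37:
            return self.hairpin_loop_dG37[length]
        # Jacobson-Stockmayer extrapolation beyond the tabulated lengths
        import math

        lmax = max(self.hairpin_loop_dG37)
        return self.hairpin_loop_dG37[lmax] + 1.75 * 1.9872e-3 * 310.15 * math.log(
            length / lmax
        )


def load_default_params() -> NNParamTable:
    """The bundled Turner-2004-style dG37 table."""
    ref = resources.files("ribopinch.data") / "nn_turner2004_dG37.csv"
    with resources.as_file(ref) as path:
        return NNParamTable.from_csv(path)


def helix_dG37(
    h: HelixDuplex,
    params: NNParamTable | None = None,
    include_loop: bool = False,
) -> float:
    """Folding free energy dG37 of a contiguous helix, kcal/mol.

    Sum of duplex initiation, the n-1 stacking terms, terminal A-U/G-U
    penalties at both helix ends, and — with ``include_loop`` and a
    ``closing_loop`` length on the duplex — the hairpin-loop penalty.
    More negative is more stable.
    """
    if params is None:
        params = load_default_params()
    pairs = h.pairs
    dG = params.init_dG37
    for outer, inner in zip(pairs[:-1], pairs[1:]):
        dG += params.stack(outer, inner)
    for end in (pairs[0], pairs[-1]):
        if end in _AU_GU_PAIRS:
            dG += params.terminal_AU_penalty
    if include_loop:
        if h.closing_loop is None:
            raise ValidationError("include_loop requires a closing_loop length")
        dG += params.loop_penalty(h.closing_loop)
    return dG


def info_bits(n_bp: int) -> float:
    """Information content of an n-bp helix at 2 bits per base pair."""
    if n_bp < 0:
        raise ValidationError(f"base-pair count must be >= 0, got {n_bp}")
    return 2.0 * n_bp


def parse_construct_fasta(path) -> list:
    """Read helix duplexes from FASTA.

    Two dialects, detected per record:

    * paired records — consecutive records with headers ``id/5`` and
      ``id/3`` (or two consecutive records sharing a bare id) give the
      two strands of one construct;
    * ampersand records — a single record whose sequence contains ``&``
      separating the two strands (both written 5'->3').

    DNA-style T is normalized to U with a logged warning.
    """
    from Bio import SeqIO

    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValidationError(f"no FASTA records in {path}")
    duplexes: list[HelixDuplex] = []
    pending = None  # (id, strand5) awaiting its partner
    for rec in records:
        seq = str(rec.seq)
        if "&" in seq:
            if pending is not None:
                raise ValidationError(
                    f"record {pending[0]!r} is missing its partner strand"
                )
            s5, s3 = seq.split("&", 1)
            duplexes.append(
                HelixDuplex(strand5=s5, strand3=s3, construct_id=rec.id)
            )
            continue
        base_id = rec.id.rsplit("/", 1)[0] if "/" in rec.id else rec.id
        if pending is None:
            pending = (base_id, seq)
        else:
            pid, s5 = pending
            if base_id != pid:
                raise ValidationError(
                    f"unpaired FASTA records: {pid!r} followed by {base_id!r}"
                )
            duplexes.append(HelixDuplex(strand5=s5, strand3=seq, construct_id=pid))
            pending = None
    if pending is not None:
        raise ValidationError(f"record {pending[0]!r} is missing its partner strand")
    return duplexes
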