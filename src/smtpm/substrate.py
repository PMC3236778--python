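"""Fork DNA substrate model for tethered-particle-motion unwinding assays.

A TPM unwinding substrate is a partially duplex DNA tether built by annealing
short partner oligonucleotides onto a scaffold strand.  One partner carries the
bead label (biotin) and forms the unwindable duplex; the scaffold's unpaired 5'
tail is the helicase loading site.  All derived geometry (duplex length, 5'
overhang, nick count, single-stranded content as unwinding proceeds) follows
from oligo lengths and anneal registers alone — sequences are optional and,
when supplied, are only checked for complementarity.

Coordinates are 1-based inclusive positions on the scaffold strand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "OligoSpec",
    "SubstrateSpec",
    "TetherComposition",
    "anneal",
    "composition_at",
    "read_oligos_fasta",
    "substrate_from_fasta",
    "substrate_summary",
    "fork_ac90",
    "mimic_unwound",
]

#: 145 nt TG-rich scaffold strand of the fork-AC90 substrate (5'->3').
SCAFFOLD_A = (
    "TTTTTTTTTTTTTTTCCAGTCACAGAAAAGCATCTTATGTGACCGTCTCTGTGTGCTGGT"
    "GGGTGTGTGTGTGCTGGTGGGTGTGTGTGTGCTGGTGGGTGTGTGTGTGTGTGTGTGCAG"
    "GTGTAGACTACAGCGTGAGCTATGA"
)


@dataclass(frozen=True)
class OligoSpec:
    """One oligonucleotide of an annealed substrate.

    ``anneal_start``/``anneal_end`` give the 1-based inclusive interval on the
    scaffold to which this oligo is paired.  The paired interval may be shorter
    than the oligo; the unpaired excess is a single-stranded overhang of the
    partner itself (e.g. the bead-proximal tail of a mimicked-unwound
    substrate).
    """

    name: str
    length: int
    sequence: Optional[str] = None
    label5: Optional[str] = None
    label3: Optional[str] = None
    anneal_start: Optional[int] = None
    anneal_end: Optional[int] = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"oligo {self.name!r}: length must be >= 1")
        if self.sequence is not None:
            object.__setattr__(self, "sequence", self.sequence.upper())
            if len(self.sequence) != self.length:
                raise ValueError(
                    f"oligo {self.name!r}: sequence length "
                    f"{len(self.sequence)} != declared length {self.length}"
                )
        if (self.anneal_start is None) != (self.anneal_end is None):
            raise ValueError(
                f"oligo {self.name!r}: anneal_start and anneal_end must be "
                "given together"
            )
        if self.anneal_start is not None:
            if self.anneal_start < 1 or self.anneal_end < self.anneal_start:
                raise ValueError(
                    f"oligo {self.name!r}: invalid anneal interval "
                    f"{self.anneal_start}-{self.anneal_end}"
                )
            if self.paired_length > self.length:
                raise ValueError(
                    f"oligo {self.name!r}: paired interval "
                    f"({self.paired_length} nt) exceeds oligo length "
                    f"({self.length} nt)"
                )

    @property
    def paired_length(self) -> int:
        """Number of scaffold positions this oligo pairs with (0 if none)."""
        if self.anneal_start is None:
            return 0
        return self.anneal_end - self.anneal_start + 1

    @property
    def unpaired_length(self) -> int:
        """Single-stranded nt of this oligo not annealed to the scaffold."""
        return self.length - self.paired_length


@dataclass(frozen=True)
class SubstrateSpec:
    """An annealed substrate with derived duplex/overhang/nick geometry."""

    name: str
    scaffold: OligoSpec
    partners: tuple  # OligoSpec, sorted by anneal_start
    duplex_bp: int
    overhang5_nt: int
    nicks: int
    unwindable_bp: int

    @property
    def ss_nt(self) -> int:
        """Total single-stranded nt on the tether path before unwinding."""
        scaffold_unpaired = self.scaffold.length - self.duplex_bp
        partner_unpaired = sum(p.unpaired_length for p in self.partners)
        return scaffold_unpaired + partner_unpaired


@dataclass(frozen=True)
class TetherComposition:
    """Duplex/single-strand make-up of the tether at a given unwinding state."""

    duplex_bp: int
    ss_nt: int
    bead_attached: bool


def _check_complementarity(scaffold: OligoSpec, partner: OligoSpec) -> None:
    """If both sequences are known, the partner must contain the exact
    reverse complement of the scaffold interval it claims to pair with."""
    if scaffold.sequence is None or partner.sequence is None:
        return
    s, e = partner.anneal_start, partner.anneal_end
    target = str(Seq(scaffold.sequence[s - 1 : e]).reverse_complement())
    if target not in partner.sequence:
        raise ValueError(
            f"oligo {partner.name!r} is not complementary to scaffold "
            f"positions {s}-{e}"
        )


def anneal(
    scaffold: OligoSpec,
    partners: Sequence[OligoSpec],
    name: str = "substrate",
    unwindable_bp: Optional[int] = None,
) -> SubstrateSpec:
    """Assemble a substrate from a scaffold and annealed partner oligos.

    Partner anneal intervals must lie inside the scaffold and not overlap.
    Derived quantities:

    * ``duplex_bp`` — sum of paired interval lengths,
    * ``overhang5_nt`` — unpaired scaffold nt 5' of the first paired position,
    * ``nicks`` — junctions where two partners abut with no gap,
    * ``unwindable_bp`` — paired length of the bead-labelled partner (the one
      whose 3' or 5' label contains "bio"); override with ``unwindable_bp``.

    The partner list is order-independent.
    """
    parts = sorted(partners, key=lambda p: (p.anneal_start is None, p.anneal_start or 0))
    prev_end = 0
    nicks = 0
    duplex = 0
    for p in parts:
        if p.anneal_start is None:
            raise ValueError(f"partner {p.name!r} has no anneal coordinates")
        if p.anneal_end > scaffold.length:
            raise ValueError(
                f"partner {p.name!r} anneal interval "
                f"{p.anneal_start}-{p.anneal_end} extends beyond the "
                f"{scaffold.length} nt scaffold"
            )
        if p.anneal_start <= prev_end:
            raise ValueError(
                f"partner {p.name!r} overlaps a previously annealed interval"
            )
        if prev_end and p.anneal_start == prev_end + 1:
            nicks += 1
        _check_complementarity(scaffold, p)
        duplex += p.paired_length
        prev_end = p.anneal_end

    if parts:
        overhang5 = parts[0].anneal_start - 1
    else:
        overhang5 = scaffold.length

    if unwindable_bp is None:
        bead_partners = [
            p
            for p in parts
            if "bio" in ((p.label3 or "") + (p.label5 or "")).lower()
        ]
        if bead_partners:
            unwindable_bp = bead_partners[0].paired_length
        elif parts:
            unwindable_bp = max(p.paired_length for p in parts)
        else:
            unwindable_bp = 0

    return SubstrateSpec(
        name=name,
        scaffold=scaffold,
        partners=tuple(parts),
        duplex_bp=duplex,
        overhang5_nt=overhang5,
        nicks=nicks,
        unwindable_bp=unwindable_bp,
    )


def composition_at(substrate: SubstrateSpec, unwound: int) -> TetherComposition:
    """Tether composition after ``unwound`` base pairs have been opened.

    Each opened base pair removes one bp of duplex and adds two nt of
    single strand along the surface-to-bead path (both strands of the opened
    pair stay in the tether until the bead-labelled strand is released).  The
    bead detaches exactly when the whole unwindable duplex is open.
    """
    if not 0 <= unwound <= substrate.unwindable_bp:
        raise ValueError(
            f"unwound={unwound} outside [0, {substrate.unwindable_bp}]"
        )
    return TetherComposition(
        duplex_bp=substrate.duplex_bp - unwound,
        ss_nt=substrate.ss_nt + 2 * unwound,
        bead_attached=unwound < substrate.unwindable_bp,
    )


# ---------------------------------------------------------------------------
# FASTA interface.  Labels and anneal registers ride in the description line
# as key=value tokens, e.g.:
#   >oligoB label5=dig anneal=128-145
#   TCATAGCTCACGCTGTAG
# ---------------------------------------------------------------------------

def _parse_tokens(description: str) -> dict:
    tokens = {}
    for tok in description.split()[1:]:
        if "=" not in tok:
            raise ValueError(f"malformed description token {tok!r}")
        key, value = tok.split("=", 1)
        tokens[key] = value
    return tokens


def read_oligos_fasta(path) -> list:
    """Read oligo definitions from an annotated FASTA file."""
    oligos = []
    for rec in SeqIO.parse(str(path), "fasta"):
        tokens = _parse_tokens(rec.description)
        start = end = None
        if "anneal" in tokens:
            a, _, b = tokens["anneal"].partition("-")
            start, end = int(a), int(b)
        oligos.append(
            OligoSpec(
                name=rec.id,
                length=len(rec.seq),
                sequence=str(rec.seq),
                label5=tokens.get("label5"),
                label3=tokens.get("label3"),
                anneal_start=start,
                anneal_end=end,
            )
        )
    if not oligos:
        raise ValueError(f"no oligo records in {path}")
    return oligos


def substrate_from_fasta(path, name: Optional[str] = None) -> SubstrateSpec:
    """Build a substrate from a FASTA file; the record without an ``anneal``
    token is the scaffold."""
    oligos = read_oligos_fasta(path)
    scaffolds = [o for o in oligos if o.anneal_start is None]
    if len(scaffolds) != 1:
        raise ValueError(
            f"expected exactly one scaffold (record without anneal=), "
            f"found {len(scaffolds)}"
        )
    scaffold = scaffolds[0]
    partners = [o for o in oligos if o.anneal_start is not None]
    return anneal(scaffold, partners, name=name or Path(str(path)).stem)


def substrate_summary(substrates: Iterable[SubstrateSpec]) -> pd.DataFrame:
    """Tabular geometry report (one row per substrate)."""
    rows = [
        {
            "name": s.name,
            "duplex_bp": s.duplex_bp,
            "overhang5_nt": s.overhang5_nt,
            "ss_nt": s.ss_nt,
            "nicks": s.nicks,
            "unwindable_bp": s.unwindable_bp,
        }
        for s in substrates
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Canonical substrates.  Partner sequences are derived as exact reverse
# complements of the scaffold intervals they pair with, so complementarity
# holds by construction; oligo C additionally keeps its biotinylated 3' end
# free in the mimic.
# ---------------------------------------------------------------------------

def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def fork_ac90() -> SubstrateSpec:
    """Fork substrate: 145 nt scaffold A, 18 nt dig-labelled B annealed at
    128-145, 90 nt biotinylated C annealed at 38-127.  Yields a 108 bp duplex
    with a 37 nt 5' overhang for helicase loading and one nick."""
    a = OligoSpec("oligoA", 145, sequence=SCAFFOLD_A)
    b = OligoSpec(
        "oligoB",
        18,
        sequence=_revcomp(SCAFFOLD_A[127:145]),
        label5="dig",
        anneal_start=128,
        anneal_end=145,
    )
    c = OligoSpec(
        "oligoC",
        90,
        sequence=_revcomp(SCAFFOLD_A[37:127]),
        label3="biotin",
        anneal_start=38,
        anneal_end=127,
    )
    return anneal(a, [b, c], name="fork-AC90")


def mimic_unwound() -> SubstrateSpec:
    """Mimicked-unwound control: scaffold A truncated to its 3'-terminal
    37 nt, with B and C annealed at the equivalent registers.  Only 19 nt of
    C remain paired, leaving a 71 nt single-stranded bead-proximal tail and a
    37 bp duplex with one nick."""
    a37 = OligoSpec("oligoA37", 37, sequence=SCAFFOLD_A[108:145])
    b = OligoSpec(
        "oligoB",
        18,
        sequence=_revcomp(SCAFFOLD_A[127:145]),
        label5="dig",
        anneal_start=20,
        anneal_end=37,
    )
    c = OligoSpec(
        "oligoC",
        90,
        sequence=_revcomp(SCAFFOLD_A[37:127]),
        label3="biotin",
        anneal_start=1,
        anneal_end=19,
    )
    return anneal(a37, [b, c], name="mimic-unwound")
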