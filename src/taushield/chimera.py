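"""Combinatorial chimera panels between repeat leading strands.

The 11-residue leading strands of tau repeat 2 (295-305, DNIKHVPGGGS) and
repeat 1 (264-274, ENLKHQPGGGK) differ at four positions and feed into the
VQIVYK amyloid core (306-311).  Enumerating every combination of those
differing positions yields the 2^4 = 16 chimeric 17-mer peptides whose
aggregation kinetics map which flanking residues shield the motif.  The
measured trend is roughly an order of magnitude of aggregation delay per
repeat-1 substitution, which ``fit_delay_trend`` quantifies as a log10
half-time slope.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy import stats

from ._tau import R1_LEADING, R2_LEADING, VQIVYK_CORE

logger = logging.getLogger(__name__)

__all__ = [
    "PeptideSpec",
    "ChimeraPanel",
    "KineticRegime",
    "diff_positions",
    "enumerate_chimeras",
    "classify_regime",
    "fit_delay_trend",
    "write_panel_fasta",
    "read_panel_fasta",
]

_AA = set("ACDEFGHIKLMNPQRSTVWY")

REGIMES = ("hours", "tens_of_hours", "hundreds_of_hours", "none")


@dataclass(frozen=True)
class PeptideSpec:
    """A synthetic peptide: sequence plus terminal-modification metadata.

    Deletion variants are encoded by omission in the sequence itself.
    """

    name: str
    sequence: str
    n_term_mod: str = "acetyl"
    c_term_mod: str = "amide"
    start_residue: int | None = None

    def __post_init__(self) -> None:
        if not self.sequence or set(self.sequence) - _AA:
            raise ValueError(f"invalid sequence {self.sequence!r}")


@dataclass(frozen=True)
class ChimeraMember:
    sequence: str
    n_subs: int
    name: str = ""


@dataclass
class ChimeraPanel:
    parent_a: str
    parent_b: str
    core: str
    fixed_mutations: dict[int, str]
    members: list[ChimeraMember]


def diff_positions(a: str, b: str) -> list[int]:
    """1-based positions at which two equal-length sequences differ."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return [i + 1 for i, (x, y) in enumerate(zip(a, b)) if x != y]


def enumerate_chimeras(
    parent_a: str = R2_LEADING,
    parent_b: str = R1_LEADING,
    core: str = VQIVYK_CORE,
    fixed_mutations: Mapping[int, str] | None = None,
) -> ChimeraPanel:
    """Enumerate all 2^d leading-strand chimeras between two parents.

    Every member is a leading strand drawing each of the d differing
    positions from parent_a or parent_b, concatenated with the core, with
    any fixed mutations (1-based positions in the concatenated peptide)
    applied afterwards.  ``n_subs`` counts parent_b residues adopted.
    Members are ordered by binary counting over the ascending differing
    positions, so the parent_a- and parent_b-derived sequences are first
    and last.

    The default arguments build the repeat-2/repeat-1 panel with the P301L
    core substitution (position 7 of the leading strand), the 16-peptide
    combinatorial panel probing VQIVYK shielding.
    """
    if fixed_mutations is None:
        fixed_mutations = {7: "L"}  # P301L in the repeat-2 frame
    positions = diff_positions(parent_a, parent_b)
    for pos, res in fixed_mutations.items():
        if pos in positions:
            raise ValueError(
                f"conflicting specification: fixed mutation at differing position {pos}"
            )
        if not 1 <= pos <= len(parent_a) + len(core):
            raise ValueError(f"fixed mutation position {pos} outside peptide")
        if res not in _AA:
            raise ValueError(f"invalid residue {res!r}")

    members: list[ChimeraMember] = []
    d = len(positions)
    for mask in range(2 ** d):
        leading = list(parent_a)
        n_subs = 0
        for bit, pos in enumerate(positions):
            if mask >> bit & 1:
                leading[pos - 1] = parent_b[pos - 1]
                n_subs += 1
        peptide = list("".join(leading) + core)
        for pos, res in fixed_mutations.items():
            peptide[pos - 1] = res
        members.append(
            ChimeraMember(sequence="".join(peptide), n_subs=n_subs,
                          name=f"chimera_{mask:0{max(d, 1)}b}")
        )
    if len({m.sequence for m in members}) != len(members):
        raise ValueError("parents produce duplicate chimeras")
    return ChimeraPanel(
        parent_a=parent_a, parent_b=parent_b, core=core,
        fixed_mutations=dict(fixed_mutations), members=members,
    )


def classify_regime(n_subs: int) -> str:
    """Kinetic regime implied by the number of repeat-1 substitutions.

    Zero or one substitution aggregates within hours; two delays the
    half-time roughly an order of magnitude to tens of hours; three to
    hundreds of hours; all four give no ThT signal within a week.
    """
    if not 0 <= n_subs <= 4:
        raise ValueError(f"n_subs {n_subs} out of range 0-4")
    return {0: "hours", 1: "hours", 2: "tens_of_hours", 3: "hundreds_of_hours", 4: "none"}[n_subs]


def fit_delay_trend(
    observations: Sequence[tuple[int, float]],
) -> tuple[float, float, float]:
    """Least-squares line of log10 half-time (hours) against substitution count.

    Censored members (non-finite or non-positive half-time, i.e. the "none"
    regime) are excluded with a logged count.  Returns (slope in log10-hours
    per substitution, intercept, r-squared).
    """
    kept = [(n, t) for n, t in observations if np.isfinite(t) and t > 0]
    n_censored = len(observations) - len(kept)
    if n_censored:
        logger.info("excluding %d censored observations", n_censored)
    if not kept:
        raise ValueError("all observations censored")
    x = np.array([n for n, _ in kept], dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("need at least 2 distinct substitution counts")
    y = np.log10([t for _, t in kept])
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue ** 2)


def write_panel_fasta(panel: ChimeraPanel, path) -> None:
    """Write panel members as FASTA; descriptions carry name and n_subs."""
    records = [
        SeqRecord(Seq(m.sequence), id=m.name or f"member_{i}",
                  description=f"n_subs={m.n_subs}")
        for i, m in enumerate(panel.members)
    ]
    SeqIO.write(records, path, "fasta")


def read_panel_fasta(path) -> list[ChimeraMember]:
    members = []
    for rec in SeqIO.parse(str(path), "fasta"):
        n_subs = 0
        for token in rec.description.split():
            if token.startswith("n_subs="):
                n_subs = int(token.split("=", 1)[1])
        members.append(ChimeraMember(sequence=str(rec.seq), n_subs=n_subs, name=rec.id))
    return members
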