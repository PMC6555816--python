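"""Cross-linking mass-spectrometry contact-map analysis.

Takes post-search cross-link identification tables (xQuest-style exports:
one row per identified lysine-lysine link with QC metrics), applies the
manual validation filters, builds per-condition consensus maps across
replicates, classifies links into sequence sectors (N-term / C-term / N-C,
with an R2R3 inter-repeat flag), and compares retention across temperatures
and genotypes.  Also provides the DSS d0/d12 isotope-pair mass arithmetic
used to extract spectral pairs upstream.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from pyteomics import mass as _pmass

logger = logging.getLogger(__name__)

__all__ = [
    "CrossLinkRecord",
    "FilterCriteria",
    "ConsensusLink",
    "SectorScheme",
    "SectorSummary",
    "DssMassSet",
    "compute_dss_masses",
    "canonicalize",
    "apply_filters",
    "build_consensus",
    "assign_sector",
    "summarize_sectors",
    "differential_retention",
    "export_contact_matrix",
    "read_crosslink_tsv",
    "write_consensus_tsv",
    "write_contact_matrix",
]

#: quenched/amidated mono-link mass as configured in xQuest search settings.
#: It is not derivable from a simple DSS adduct (an ammonia-quenched amide
#: computes to 155.094629 Da), so it is carried as a configured constant.
MONOLINK_ALT_DA = 155.096428


class SelfLinkError(ValueError):
    """A record with res_a == res_b is a mono-link, not a cross-link."""


@dataclass(frozen=True)
class CrossLinkRecord:
    """One identified lysine-lysine cross-link with its QC metrics.

    Residue positions are absolute 1-based 2N4R numbering.  Per-peptide
    fields (``pep_len``, ``frag_ions``, ``contig_frags``) follow the a/b
    order of the residue pair.
    """

    replicate_id: str
    condition: str
    temperature_c: float
    res_a: int
    res_b: int
    score: float
    mass_error_ppm: float
    tic_pct: float
    pep_len_a: int
    pep_len_b: int
    frag_ions_a: int
    frag_ions_b: int
    contig_frags_a: int
    contig_frags_b: int
    nseen: int


@dataclass(frozen=True)
class FilterCriteria:
    """Post-search manual-validation thresholds for cross-link IDs."""

    min_score: float = 25.0
    ppm_min: float = -2.2
    ppm_max: float = 3.8
    min_tic_pct: float = 10.0
    min_pep_len: int = 6
    min_frag_ions: int = 4
    min_contig_frags: int = 3

    def __post_init__(self) -> None:
        if not self.ppm_min < self.ppm_max:
            raise ValueError("ppm_min must be below ppm_max")


@dataclass(frozen=True)
class ConsensusLink:
    """A residue pair present in at least the required number of replicates."""

    res_a: int
    res_b: int
    condition: str
    temperature_c: float
    n_replicates_present: int
    mean_frequency: float


@dataclass(frozen=True)
class SectorScheme:
    """Sequence sectors for classifying contacts in the tau RD construct.

    The N-/C-terminal split is at the 310/311 boundary, immediately after
    the VQIVYK motif opens; the R2/R3 windows flag inter-repeat contacts
    spanning the amyloid-motif interface.
    """

    nterm_range: tuple[int, int] = (243, 310)
    cterm_range: tuple[int, int] = (311, 380)
    r2_range: tuple[int, int] = (275, 305)
    r3_range: tuple[int, int] = (306, 336)


@dataclass
class SectorSummary:
    """Per (condition, temperature) consensus-link counts by sector."""

    condition: str
    temperature_c: float
    n_term: int = 0
    c_term: int = 0
    n_c: int = 0
    r2r3: int = 0

    @property
    def total(self) -> int:
        return self.n_term + self.c_term + self.n_c


@dataclass(frozen=True)
class DssMassSet:
    """Monoisotopic mass constants for the DSS d0/d12 cross-linker."""

    pair_delta_da: float
    light_shift_da: float
    monolink_hydrolyzed_da: float
    monolink_alt_da: float


def compute_dss_masses(monolink_alt_da: float = MONOLINK_ALT_DA) -> DssMassSet:
    """DSS isotope-pair and mono-link mass arithmetic from atomic masses.

    The d12-d0 precursor difference is twelve deuterium-for-hydrogen
    exchanges; the light cross-linker shift is the suberate bridge C8H10O2;
    the hydrolyzed mono-link adds one water.
    """
    mono_h = _pmass.nist_mass["H"][1][0]
    mono_d = _pmass.nist_mass["H"][2][0]
    light = _pmass.calculate_mass(formula="C8H10O2")
    water = _pmass.calculate_mass(formula="H2O")
    return DssMassSet(
        pair_delta_da=12.0 * (mono_d - mono_h),
        light_shift_da=light,
        monolink_hydrolyzed_da=light + water,
        monolink_alt_da=monolink_alt_da,
    )


def canonicalize(record: CrossLinkRecord) -> CrossLinkRecord:
    """Order the residue pair as res_a <= res_b, swapping per-peptide QC fields."""
    if record.res_a == record.res_b:
        raise SelfLinkError(
            f"self-link at residue {record.res_a}: route to mono-link handling"
        )
    if record.res_a <= record.res_b:
        return record
    return replace(
        record,
        res_a=record.res_b,
        res_b=record.res_a,
        pep_len_a=record.pep_len_b,
        pep_len_b=record.pep_len_a,
        frag_ions_a=record.frag_ions_b,
        frag_ions_b=record.frag_ions_a,
        contig_frags_a=record.contig_frags_b,
        contig_frags_b=record.contig_frags_a,
    )


def _peptide_ok(frag_ions: int, contig_frags: int, criteria: FilterCriteria) -> bool:
    # each peptide must carry >= 4 assigned fragment ions OR >= 3 contiguous
    return frag_ions >= criteria.min_frag_ions or contig_frags >= criteria.min_contig_frags


def record_passes(record: CrossLinkRecord, criteria: FilterCriteria) -> bool:
    """Evaluate the full conjunction of validation criteria on one record."""
    return (
        record.score > criteria.min_score
        and criteria.ppm_min <= record.mass_error_ppm <= criteria.ppm_max
        and record.tic_pct > criteria.min_tic_pct
        and record.pep_len_a >= criteria.min_pep_len
        and record.pep_len_b >= criteria.min_pep_len
        and _peptide_ok(record.frag_ions_a, record.contig_frags_a, criteria)
        and _peptide_ok(record.frag_ions_b, record.contig_frags_b, criteria)
    )


def apply_filters(
    records: Sequence[CrossLinkRecord],
    criteria: FilterCriteria | None = None,
) -> list[CrossLinkRecord]:
    """Retain records satisfying every validation criterion, preserving order.

    Criteria: score strictly above the minimum, mass error inside the ppm
    window (inclusive), %TIC strictly above the minimum, both peptides at
    least the minimum length, and each peptide with enough assigned
    fragment ions (or enough contiguous ones).
    """
    criteria = criteria or FilterCriteria()
    return [r for r in records if record_passes(r, criteria)]


def build_consensus(
    records: Sequence[CrossLinkRecord],
    required_count: int = 5,
    n_replicates: int = 5,
) -> list[ConsensusLink]:
    """Consense filtered records across replicates of one condition/temperature.

    A residue pair enters the consensus when it is identified in at least
    ``required_count`` distinct replicates (default: all five of five).
    ``mean_frequency`` is the arithmetic mean of the per-replicate spectral
    frequency (``nseen``) over the replicates in which the pair appears; a
    pair identified by multiple rows within one replicate counts once, with
    that replicate's frequency taken as the maximum row ``nseen``.
    """
    if required_count > n_replicates:
        raise ValueError("required_count cannot exceed n_replicates")
    if not records:
        raise ValueError("no replicates: empty record set")
    keys = {(r.condition, r.temperature_c) for r in records}
    if len(keys) != 1:
        raise ValueError(f"records span multiple condition/temperature groups: {keys}")
    condition, temperature_c = next(iter(keys))

    # pair -> replicate -> max nseen
    per_pair: dict[tuple[int, int], dict[str, int]] = {}
    for r in records:
        if r.res_a > r.res_b:
            raise ValueError("records must be canonicalized before consensus")
        reps = per_pair.setdefault((r.res_a, r.res_b), {})
        reps[r.replicate_id] = max(reps.get(r.replicate_id, 0), r.nseen)

    out = []
    for (a, b), reps in sorted(per_pair.items()):
        if len(reps) >= required_count:
            out.append(
                ConsensusLink(
                    res_a=a,
                    res_b=b,
                    condition=condition,
                    temperature_c=temperature_c,
                    n_replicates_present=len(reps),
                    mean_frequency=float(np.mean(list(reps.values()))),
                )
            )
    return out


def assign_sector(
    res_a: int, res_b: int, scheme: SectorScheme | None = None
) -> tuple[str, bool]:
    """Classify a contact as N-term, C-term or N-C, with the R2R3 flag.

    N-term: both residues within the N-terminal sector (<= 310); C-term:
    both within 311-380; N-C: spanning the boundary.  The R2R3 flag marks
    inter-repeat contacts with one residue in the R2 window and the other
    in the R3 window.
    """
    scheme = scheme or SectorScheme()
    lo = min(res_a, res_b)
    hi = max(res_a, res_b)
    n_lo, n_hi = scheme.nterm_range
    c_lo, c_hi = scheme.cterm_range
    for r in (lo, hi):
        if not (n_lo <= r <= n_hi or c_lo <= r <= c_hi):
            raise ValueError(f"residue {r} out of range {n_lo}-{c_hi}")
    if hi <= n_hi:
        sector = "N-term"
    elif lo >= c_lo:
        sector = "C-term"
    else:
        sector = "N-C"
    r2_lo, r2_hi = scheme.r2_range
    r3_lo, r3_hi = scheme.r3_range
    in_r2 = lambda r: r2_lo <= r <= r2_hi  # noqa: E731
    in_r3 = lambda r: r3_lo <= r <= r3_hi  # noqa: E731
    r2r3 = (in_r2(lo) and in_r3(hi)) or (in_r2(hi) and in_r3(lo))
    return sector, r2r3


def summarize_sectors(
    links: Iterable[ConsensusLink], scheme: SectorScheme | None = None
) -> list[SectorSummary]:
    """Count consensus links per sector per (condition, temperature)."""
    scheme = scheme or SectorScheme()
    groups: dict[tuple[str, float], SectorSummary] = {}
    seen: set[tuple[str, float, int, int]] = set()
    for link in links:
        key = (link.condition, link.temperature_c)
        summary = groups.setdefault(key, SectorSummary(*key))
        dedup_key = (link.condition, link.temperature_c, link.res_a, link.res_b)
        if dedup_key in seen:
            continue
        seen.add(dedup_key)
        sector, r2r3 = assign_sector(link.res_a, link.res_b, scheme)
        if sector == "N-term":
            summary.n_term += 1
        elif sector == "C-term":
            summary.c_term += 1
        else:
            summary.n_c += 1
        if r2r3:
            summary.r2r3 += 1
    return list(groups.values())


def differential_retention(
    summaries_ref: Sequence[SectorSummary],
    summaries_alt: Sequence[SectorSummary],
    baseline_temperature_c: float = 37.0,
) -> pd.DataFrame:
    """Compare sector-count retention across temperature and genotype.

    For each sector and temperature the table reports the within-genotype
    retained fraction relative to the 37 degC baseline, plus the alt/ref
    count ratio at the matched temperature.  A 0/0 fraction is reported as
    NaN (undefined).
    """

    def _table(summaries: Sequence[SectorSummary]) -> pd.DataFrame:
        rows = []
        for s in summaries:
            rows.append(
                {
                    "temperature_c": s.temperature_c,
                    "N-term": s.n_term,
                    "C-term": s.c_term,
                    "N-C": s.n_c,
                    "R2R3": s.r2r3,
                    "total": s.total,
                }
            )
        return pd.DataFrame(rows).set_index("temperature_c").sort_index()

    ref = _table(summaries_ref)
    alt = _table(summaries_alt)
    if not ref.index.equals(alt.index):
        raise ValueError("summaries cover different temperature sets")
    if baseline_temperature_c not in ref.index:
        raise ValueError(f"no baseline temperature {baseline_temperature_c} degC")

    sectors = ["N-term", "C-term", "N-C", "R2R3", "total"]
    rows = []
    for temp in ref.index:
        for sector in sectors:
            r, a = ref.loc[temp, sector], alt.loc[temp, sector]
            r0 = ref.loc[baseline_temperature_c, sector]
            a0 = alt.loc[baseline_temperature_c, sector]
            rows.append(
                {
                    "sector": sector,
                    "temperature_c": temp,
                    "ref_count": int(r),
                    "alt_count": int(a),
                    "ref_retained_fraction": r / r0 if r0 else np.nan,
                    "alt_retained_fraction": a / a0 if a0 else np.nan,
                    # 0/0 -> NaN (undefined); x/0 with x>0 -> inf
                    "alt_over_ref_ratio": a / r if r else (np.nan if a == 0 else np.inf),
                }
            )
    return pd.DataFrame(rows)


def export_contact_matrix(
    links: Iterable[ConsensusLink], residue_range: tuple[int, int] = (244, 380)
) -> pd.DataFrame:
    """Dense symmetric residue-by-residue matrix of consensus mean frequencies."""
    lo, hi = residue_range
    idx = np.arange(lo, hi + 1)
    mat = pd.DataFrame(0.0, index=idx, columns=idx)
    for link in links:
        a, b = sorted((link.res_a, link.res_b))
        mat.loc[a, b] = link.mean_frequency
        mat.loc[b, a] = link.mean_frequency
    return mat


# ---------------------------------------------------------------------------
# Tabular I/O

_TSV_COLUMNS = [
    "replicate_id", "condition", "temperature_c", "res_a", "res_b", "score",
    "mass_error_ppm", "tic_pct", "pep_len_a", "pep_len_b", "frag_ions_a",
    "frag_ions_b", "contig_frags_a", "contig_frags_b", "nseen",
]


def read_crosslink_tsv(path) -> list[CrossLinkRecord]:
    """Read a cross-link identification table (tab-delimited, '#' comments).

    An optional boolean ``decoy`` column is dropped with a logged count
    (decoy/FDR modelling happens upstream of these tables).
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    if "decoy" in df.columns:
        n_decoy = int(df["decoy"].astype(bool).sum())
        if n_decoy:
            logger.info("dropping %d decoy rows", n_decoy)
        df = df.loc[~df["decoy"].astype(bool)].drop(columns="decoy")
    missing = set(_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    records = [
        CrossLinkRecord(
            replicate_id=str(row.replicate_id),
            condition=str(row.condition),
            temperature_c=float(row.temperature_c),
            res_a=int(row.res_a),
            res_b=int(row.res_b),
            score=float(row.score),
            mass_error_ppm=float(row.mass_error_ppm),
            tic_pct=float(row.tic_pct),
            pep_len_a=int(row.pep_len_a),
            pep_len_b=int(row.pep_len_b),
            frag_ions_a=int(row.frag_ions_a),
            frag_ions_b=int(row.frag_ions_b),
            contig_frags_a=int(row.contig_frags_a),
            contig_frags_b=int(row.contig_frags_b),
            nseen=int(row.nseen),
        )
        for row in df.itertuples(index=False)
    ]
    return [canonicalize(r) for r in records]


def write_crosslink_tsv(records: Sequence[CrossLinkRecord], path) -> None:
    df = pd.DataFrame([vars(r) for r in records], columns=_TSV_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def write_consensus_tsv(
    links: Sequence[ConsensusLink], path, scheme: SectorScheme | None = None
) -> None:
    scheme = scheme or SectorScheme()
    rows = []
    for link in links:
        sector, r2r3 = assign_sector(link.res_a, link.res_b, scheme)
        rows.append({**vars(link), "sector": sector, "r2r3": int(r2r3)})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_sector_summary_tsv(summaries: Sequence[SectorSummary], path) -> None:
    rows = [
        {
            "condition": s.condition,
            "temperature_c": s.temperature_c,
            "n_term": s.n_term,
            "c_term": s.c_term,
            "n_c": s.n_c,
            "r2r3": s.r2r3,
            "total": s.total,
        }
        for s in summaries
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_contact_matrix(matrix: pd.DataFrame, path) -> None:
    """Whitespace-delimited square matrix with a one-line residue-range header."""
    lo, hi = matrix.index[0], matrix.index[-1]
    with open(path, "w") as fh:
        fh.write(f"# contact matrix, residues {lo}-{hi}\n")
        np.savetxt(fh, matrix.to_numpy(), fmt="%.6g")
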