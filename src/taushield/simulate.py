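"""Synthetic-data generators with known ground truth for every pipeline stage.

Each generator emulates one instrument output consumed by the analysis
modules — xQuest-style cross-link tables, plate-reader ThT time courses,
multi-model CA ensembles, and flow-cytometry event tables — with the
injected ground truth (per-sector contact survival, half-times, hairpin
fractions, spill fractions, positive fractions) recorded alongside so that
recovery can be checked.  All generators are deterministic under a seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from ._tau import lysine_positions
from .geometry import Conformation, Ensemble
from .kinetics import ThTTrace, boltzmann
from .fret import FlowEventTable
from .xlms import CrossLinkRecord, FilterCriteria, SectorScheme, assign_sector

__all__ = [
    "ContactModel",
    "KineticsSpec",
    "EnsembleSpec",
    "FlowSpec",
    "gen_crosslink_table",
    "gen_tht_traces",
    "gen_ensemble",
    "ideal_hairpin",
    "ideal_extended",
    "gen_flow_events",
]


# ---------------------------------------------------------------------------
# XL-MS tables

@dataclass
class ContactModel:
    """Ground-truth contact model for synthetic cross-link tables.

    True contacts are lysine pairs of the packaged tau RD sequence, each
    present with a per-sector base probability; per-replicate presence at a
    given temperature is Bernoulli with the per-(sector, temperature)
    survival probability, optionally damped for mutant genotypes in the
    N-terminal / inter-repeat sectors (the heat-lability phenotype).
    """

    condition: str = "WT"
    base_contact_probability: dict[str, float] = field(
        default_factory=lambda: {"N-term": 0.5, "C-term": 0.5, "N-C": 0.3}
    )
    survival: dict[str, dict[float, float]] = field(
        default_factory=lambda: {
            "N-term": {37.0: 1.0, 50.0: 0.85, 75.0: 0.7},
            "C-term": {37.0: 1.0, 50.0: 0.95, 75.0: 0.9},
            "N-C": {37.0: 1.0, 50.0: 0.7, 75.0: 0.5},
        }
    )
    genotype_modifier: float = 1.0
    mean_nseen: float = 4.0
    decoy_fraction: float = 0.0
    scheme: SectorScheme = field(default_factory=SectorScheme)

    def true_links(self, rng: np.random.Generator) -> list[tuple[int, int, str]]:
        lys = lysine_positions()
        links = []
        for a, b in combinations(lys, 2):
            sector, _ = assign_sector(a, b, self.scheme)
            if rng.random() < self.base_contact_probability.get(sector, 0.0):
                links.append((a, b, sector))
        return links


def _passing_qc(rng: np.random.Generator, criteria: FilterCriteria) -> dict:
    """QC fields guaranteed to satisfy every filter criterion."""
    return {
        "score": float(rng.uniform(criteria.min_score + 1.0, criteria.min_score + 25.0)),
        "mass_error_ppm": float(rng.uniform(criteria.ppm_min, criteria.ppm_max)),
        "tic_pct": float(rng.uniform(criteria.min_tic_pct + 2.0, criteria.min_tic_pct + 30.0)),
        "pep_len_a": int(rng.integers(criteria.min_pep_len, 21)),
        "pep_len_b": int(rng.integers(criteria.min_pep_len, 21)),
        "frag_ions_a": int(rng.integers(criteria.min_frag_ions, 9)),
        "frag_ions_b": int(rng.integers(criteria.min_frag_ions, 9)),
        "contig_frags_a": int(rng.integers(criteria.min_contig_frags, 7)),
        "contig_frags_b": int(rng.integers(criteria.min_contig_frags, 7)),
    }


def _decoy_qc(rng: np.random.Generator, criteria: FilterCriteria) -> dict:
    """QC fields failing exactly one randomly chosen criterion."""
    qc = _passing_qc(rng, criteria)
    fail = rng.integers(0, 5)
    if fail == 0:
        qc["score"] = float(rng.uniform(criteria.min_score - 5.0, criteria.min_score))
    elif fail == 1:
        lo, hi = criteria.ppm_min, criteria.ppm_max
        qc["mass_error_ppm"] = float(
            rng.choice([rng.uniform(lo - 3.0, lo - 0.01), rng.uniform(hi + 0.01, hi + 3.0)])
        )
    elif fail == 2:
        qc["tic_pct"] = float(rng.uniform(0.0, criteria.min_tic_pct))
    elif fail == 3:
        qc["pep_len_a"] = int(rng.integers(1, criteria.min_pep_len))
    else:
        # both fragment-ion rules must fail on one peptide
        qc["frag_ions_b"] = int(rng.integers(0, criteria.min_frag_ions))
        qc["contig_frags_b"] = int(rng.integers(0, criteria.min_contig_frags))
    return qc


def gen_crosslink_table(
    model: ContactModel,
    n_replicates: int = 5,
    temperatures: Sequence[float] = (37.0, 50.0, 75.0),
    seed: int | None = None,
    criteria: FilterCriteria | None = None,
) -> tuple[list[CrossLinkRecord], pd.DataFrame]:
    """Simulate per-replicate cross-link identifications across temperatures.

    Returns the records plus a ground-truth sidecar table (one row per true
    link: residues, sector, and per-temperature survival probability used).
    True links draw QC fields that pass all filters; decoy rows
    (``model.decoy_fraction`` of true-link rows) fail at least one.
    """
    criteria = criteria or FilterCriteria()
    rng = np.random.default_rng(seed)
    links = model.true_links(rng)
    records: list[CrossLinkRecord] = []
    truth_rows = []
    for a, b, sector in links:
        row = {"res_a": a, "res_b": b, "sector": sector}
        for temp in temperatures:
            p = model.survival[sector][temp]
            if model.genotype_modifier != 1.0 and sector in ("N-term", "N-C") and temp > 37.0:
                p *= model.genotype_modifier
            p = min(max(p, 0.0), 1.0)
            row[f"survival_{temp:g}"] = p
            for rep in range(1, n_replicates + 1):
                if rng.random() >= p:
                    continue
                nseen = 1 + rng.poisson(max(model.mean_nseen - 1.0, 0.0))
                records.append(
                    CrossLinkRecord(
                        replicate_id=f"rep{rep}",
                        condition=model.condition,
                        temperature_c=float(temp),
                        res_a=a,
                        res_b=b,
                        nseen=int(nseen),
                        **_passing_qc(rng, criteria),
                    )
                )
                if rng.random() < model.decoy_fraction:
                    records.append(
                        CrossLinkRecord(
                            replicate_id=f"rep{rep}",
                            condition=model.condition,
                            temperature_c=float(temp),
                            res_a=a,
                            res_b=b,
                            nseen=int(max(1, rng.poisson(1.0))),
                            **_decoy_qc(rng, criteria),
                        )
                    )
        truth_rows.append(row)
    return records, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# ThT traces

@dataclass
class KineticsSpec:
    """Ground truth for one synthetic ThT condition."""

    t_half: float = 10.0
    tau_slope: float = 1.0
    baseline: float = 50.0
    amplitude: float = 400.0
    noise_sd: float = 0.0
    duration: float = 48.0
    dt: float = 1.0 / 12.0  # 5-minute scans
    n_replicates: int = 3
    condition: str = "synthetic"
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.t_half < self.duration:
            raise ValueError("t_half must lie inside the observed duration")
        if self.dt <= 0:
            raise ValueError("dt must be positive")


def gen_tht_traces(spec: KineticsSpec) -> tuple[list[ThTTrace], list[ThTTrace]]:
    """Boltzmann-sigmoid traces plus blank wells (baseline + noise)."""
    rng = np.random.default_rng(spec.seed)
    times = np.arange(0.0, spec.duration + spec.dt / 2, spec.dt)
    ideal = boltzmann(times, spec.baseline, spec.amplitude, spec.t_half, spec.tau_slope)
    traces = [
        ThTTrace(
            times=times,
            fluorescence=ideal + rng.normal(0.0, spec.noise_sd, times.size)
            if spec.noise_sd > 0
            else ideal.copy(),
            condition=spec.condition,
            replicate=f"rep{i + 1}",
        )
        for i in range(spec.n_replicates)
    ]
    blanks = [
        ThTTrace(
            times=times,
            fluorescence=np.full(times.size, spec.baseline)
            + (rng.normal(0.0, spec.noise_sd, times.size) if spec.noise_sd > 0 else 0.0),
            condition="blank",
            replicate=f"blank{i + 1}",
            is_blank=True,
        )
        for i in range(3)
    ]
    return traces, blanks


# ---------------------------------------------------------------------------
# Conformational ensembles

@dataclass
class EnsembleSpec:
    """Ground truth for a synthetic hairpin/extended conformational mixture."""

    n_conformations: int = 100
    hairpin_fraction: float = 0.5
    noise_sd: float = 0.3
    strand_rise: float = 3.8
    strand_separation: float = 5.0
    turn_length: int = 4
    residue_start: int = 295
    residue_end: int = 311
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.hairpin_fraction <= 1.0:
            raise ValueError("hairpin_fraction must be in [0, 1]")


def ideal_extended(spec: EnsembleSpec | None = None) -> Conformation:
    """Straight CA chain with the canonical 3.8 angstrom per-residue rise."""
    spec = spec or EnsembleSpec()
    n = spec.residue_end - spec.residue_start + 1
    coords = np.zeros((n, 3))
    coords[:, 0] = np.arange(n) * spec.strand_rise
    return Conformation(
        residue_numbers=np.arange(spec.residue_start, spec.residue_end + 1),
        ca_coords=coords,
        label="extended",
    )


def ideal_hairpin(spec: EnsembleSpec | None = None) -> Conformation:
    """Ideal antiparallel two-strand CA hairpin over the residue range.

    The first and last residues sit directly across the two strands at the
    strand-separation distance (default 5.0 angstrom); a semicircular turn
    of ``turn_length`` residues connects the strands.  This is the canonical
    hairpin reference for the deviation collective variable.
    """
    spec = spec or EnsembleSpec()
    n = spec.residue_end - spec.residue_start + 1
    n_strand2 = (n - spec.turn_length) // 2
    n_strand1 = n - spec.turn_length - n_strand2
    coords = np.zeros((n, 3))
    # strand 1 along +x at y=0
    for i in range(n_strand1):
        coords[i] = (i * spec.strand_rise, 0.0, 0.0)
    # strand 2 antiparallel at y=-separation, residue n-1 under residue 0
    for j in range(n_strand2):
        coords[n - 1 - j] = (j * spec.strand_rise, -spec.strand_separation, 0.0)
    # semicircular turn joining strand1 end to strand2 start
    p1 = coords[n_strand1 - 1]
    p2 = coords[n - n_strand2]
    center = (p1 + p2) / 2.0
    radius = np.linalg.norm(p2 - p1) / 2.0
    axis = (p2 - p1) / np.linalg.norm(p2 - p1)
    # arc bulges in +x beyond the strand ends
    for k in range(1, spec.turn_length + 1):
        theta = np.pi * k / (spec.turn_length + 1)
        along = -np.cos(theta) * radius
        out = np.sin(theta) * radius
        coords[n_strand1 - 1 + k] = center + along * axis + out * np.array([1.0, 0.0, 0.0])
    return Conformation(
        residue_numbers=np.arange(spec.residue_start, spec.residue_end + 1),
        ca_coords=coords,
        label="hairpin",
    )


def gen_ensemble(spec: EnsembleSpec) -> tuple[Ensemble, pd.DataFrame]:
    """Mixture of noisy hairpin and extended conformations with labels.

    Returns the ensemble plus a sidecar frame (model_index, label) holding
    the ground-truth class of each member.
    """
    rng = np.random.default_rng(spec.seed)
    hairpin = ideal_hairpin(spec)
    extended = ideal_extended(spec)
    n_hairpin = int(round(spec.hairpin_fraction * spec.n_conformations))
    conformations = []
    labels = []
    for i in range(spec.n_conformations):
        template = hairpin if i < n_hairpin else extended
        noise = (
            rng.normal(0.0, spec.noise_sd, template.ca_coords.shape)
            if spec.noise_sd > 0
            else 0.0
        )
        conformations.append(
            Conformation(
                residue_numbers=template.residue_numbers.copy(),
                ca_coords=template.ca_coords + noise,
                label=f"model_{i + 1}",
            )
        )
        labels.append(template.label)
    truth = pd.DataFrame({"model_index": np.arange(spec.n_conformations), "label": labels})
    return Ensemble(conformations=conformations), truth


# ---------------------------------------------------------------------------
# Flow-cytometry events

@dataclass
class FlowSpec:
    """Ground truth for synthetic biosensor flow-cytometry events.

    Channel intensities are log-normal; ``positive_median_fret`` is the
    median true FRET intensity of the positive population (the injected
    MFI).  Spill is applied linearly so that sequential compensation with
    the same fractions recovers the pre-spill intensities exactly.
    """

    n_events: int = 20000
    positive_fraction: float = 0.1
    cfp_median: float = 200.0
    cfp_sigma: float = 0.4
    yfp_median: float = 300.0
    yfp_sigma: float = 0.4
    negative_fret_median: float = 30.0
    negative_fret_sigma: float = 0.4
    positive_median_fret: float = 500.0
    positive_fret_sigma: float = 0.3
    spill_cfp_to_yfp: float = 0.1
    spill_cfp_to_fret: float = 0.15
    spill_yfp_to_fret: float = 0.05
    sample: str = "synthetic"
    replicate: str = "rep1"
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.positive_fraction <= 1.0:
            raise ValueError("positive_fraction must be in [0, 1]")


def gen_flow_events(spec: FlowSpec) -> tuple[FlowEventTable, pd.DataFrame]:
    """Raw (spill-applied) events plus ground truth per event.

    The sidecar frame carries the positive flag and the pre-spill channel
    intensities.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_events
    n_pos = int(round(spec.positive_fraction * n))
    cfp = rng.lognormal(np.log(spec.cfp_median), spec.cfp_sigma, n)
    yfp = rng.lognormal(np.log(spec.yfp_median), spec.yfp_sigma, n)
    fret = rng.lognormal(np.log(spec.negative_fret_median), spec.negative_fret_sigma, n)
    positive = np.zeros(n, dtype=bool)
    positive[:n_pos] = True
    fret[positive] = rng.lognormal(
        np.log(spec.positive_median_fret), spec.positive_fret_sigma, n_pos
    )
    # linear spill; compensation with the same fractions inverts this exactly
    yfp_raw = yfp + spec.spill_cfp_to_yfp * cfp
    fret_raw = fret + spec.spill_cfp_to_fret * cfp + spec.spill_yfp_to_fret * yfp
    events = FlowEventTable(
        cfp=cfp, yfp=yfp_raw, fret=fret_raw, sample=spec.sample, replicate=spec.replicate
    )
    truth = pd.DataFrame(
        {"positive": positive, "cfp_true": cfp, "yfp_true": yfp, "fret_true": fret}
    )
    return events, truth
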