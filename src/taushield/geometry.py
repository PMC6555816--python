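"""Conformational-ensemble geometry and free-energy analysis.

Operates on CA-only conformations of the tau repeat domain (or peptide
fragments thereof): optimal rigid-body superposition, pairwise RMSD
matrices, inter-repeat CA-CA end-to-end distances, an RMSD-to-canonical-
hairpin collective variable, Boltzmann-inverted free-energy profiles with
bootstrap confidence intervals, and k-medoids clustering of RMSD matrices.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

#: Boltzmann constant in kJ/mol/K
KB_KJ_PER_MOL_K = 0.0083145

__all__ = [
    "Conformation",
    "Ensemble",
    "FESProfile",
    "DEFAULT_INTERFACE_PAIRS",
    "kabsch_superpose",
    "rmsd",
    "pairwise_rmsd_matrix",
    "end_to_end_distances",
    "hairpin_deviation",
    "fes_from_cv",
    "basin_analysis",
    "cluster_medoids",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
]

#: inter-repeat CA-CA pairs bracketing each repeat's leading strand + motif
DEFAULT_INTERFACE_PAIRS = [(264, 280), (295, 311), (327, 343), (359, 375)]


@dataclass
class Conformation:
    """Ordered CA coordinates (angstrom) over ascending residue numbers."""

    residue_numbers: np.ndarray
    ca_coords: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        self.ca_coords = np.asarray(self.ca_coords, dtype=float)
        if self.ca_coords.shape != (self.residue_numbers.size, 3):
            raise ValueError("one coordinate triple required per residue")
        if np.any(np.diff(self.residue_numbers) <= 0):
            raise ValueError("residue numbers must be ascending")


@dataclass
class Ensemble:
    """Conformations over a common residue set, with optional statistical
    weights (e.g. metadynamics reweighting factors supplied externally)."""

    conformations: list[Conformation]
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.conformations:
            ref = self.conformations[0].residue_numbers
            for c in self.conformations[1:]:
                if not np.array_equal(c.residue_numbers, ref):
                    raise ValueError("conformations must share a residue set")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.size != len(self.conformations):
                raise ValueError("one weight per conformation required")
            if np.any(self.weights < 0) or self.weights.sum() <= 0:
                raise ValueError("weights must be non-negative with positive sum")

    def __len__(self) -> int:
        return len(self.conformations)


@dataclass
class FESProfile:
    """A one-dimensional free-energy profile over a collective variable.

    ``free_energy`` is min-shifted to zero over populated bins; bins with
    zero probability are flagged unpopulated (NaN), never given finite
    values.  ``ci95`` holds per-bin bootstrap half-widths in kJ/mol.
    """

    bin_centers: np.ndarray
    free_energy: np.ndarray
    ci95: np.ndarray
    populated: np.ndarray
    temperature_k: float


def _check_common(a: Conformation, b: Conformation) -> None:
    if not np.array_equal(a.residue_numbers, b.residue_numbers):
        raise ValueError("mismatched residue sets")


def kabsch_superpose(
    mobile: Conformation, reference: Conformation
) -> tuple[Conformation, np.ndarray, np.ndarray]:
    """Least-squares rigid-body superposition of mobile onto reference.

    Returns the transformed conformation, the proper rotation matrix
    (determinant +1; reflections are disallowed) and the translation.
    Degenerate point sets (fewer than 3 points, or coincident points with
    no orientational information) raise.  Collinear sets are permitted:
    the residual rotation about the line axis does not affect the fit, so
    the superposed RMSD remains well defined (the extended-chain limit of
    the hairpin collective variable relies on this).
    """
    _check_common(mobile, reference)
    X = mobile.ca_coords
    Y = reference.ca_coords
    if X.shape[0] < 3:
        raise ValueError("need at least 3 points for superposition")
    xc = X.mean(axis=0)
    yc = Y.mean(axis=0)
    H = (X - xc).T @ (Y - yc)
    U, S, Vt = np.linalg.svd(H)
    scale = max(np.linalg.norm(X - xc), np.linalg.norm(Y - yc), 1.0)
    if S[0] <= 1e-8 * scale:
        raise ValueError("degenerate (coincident) point set")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = yc - R @ xc
    moved = Conformation(
        residue_numbers=mobile.residue_numbers.copy(),
        ca_coords=(R @ X.T).T + t,
        label=mobile.label,
    )
    return moved, R, t


def rmsd(a: Conformation, b: Conformation, superpose: bool = True) -> float:
    """Root-mean-square CA deviation, after optimal superposition if flagged."""
    _check_common(a, b)
    if superpose:
        a, _, _ = kabsch_superpose(a, b)
    diff = a.ca_coords - b.ca_coords
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))


def pairwise_rmsd_matrix(ensemble: Ensemble) -> np.ndarray:
    """Symmetric zero-diagonal matrix of superposed RMSDs over all pairs."""
    n = len(ensemble)
    if n < 2:
        raise ValueError("need at least 2 conformations")
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            M[i, j] = M[j, i] = rmsd(
                ensemble.conformations[i], ensemble.conformations[j]
            )
    return M


def end_to_end_distances(
    ensemble: Ensemble, pairs: Sequence[tuple[int, int]] = None
) -> pd.DataFrame:
    """Euclidean CA-CA distance per conformation for each residue pair.

    Returns a long-format frame (pair, conformation, distance_A); summary
    statistics (median, IQR) per pair are available via groupby.
    """
    pairs = DEFAULT_INTERFACE_PAIRS if pairs is None else pairs
    rows = []
    for i, conf in enumerate(ensemble.conformations):
        index = {r: k for k, r in enumerate(conf.residue_numbers)}
        for ra, rb in pairs:
            if ra not in index or rb not in index:
                raise ValueError(f"residue pair ({ra},{rb}) missing from ensemble")
            d = float(np.linalg.norm(conf.ca_coords[index[ra]] - conf.ca_coords[index[rb]]))
            rows.append({"pair": f"{ra}-{rb}", "conformation": i, "distance_A": d})
    return pd.DataFrame(rows)


def summarize_distances(dist: pd.DataFrame) -> pd.DataFrame:
    """Median and IQR of the CA-CA distance distribution per pair."""
    def _iqr(x):
        q1, q3 = np.percentile(x, [25, 75])
        return q3 - q1

    return dist.groupby("pair")["distance_A"].agg(median="median", iqr=_iqr).reset_index()


def hairpin_deviation(conformation: Conformation, reference_hairpin: Conformation) -> float:
    """Superposed CA RMSD to the canonical hairpin: the collective variable
    over which the free-energy surface is estimated."""
    return rmsd(conformation, reference_hairpin, superpose=True)


def fes_from_cv(
    samples: np.ndarray,
    weights: np.ndarray | None = None,
    temperature_k: float = 300.0,
    bin_width: float = 0.5,
    bootstrap_b: int = 200,
    seed: int | None = None,
) -> FESProfile:
    """Boltzmann-inverted free-energy profile over a collective variable.

    Bins the (optionally weighted) samples, converts probabilities to
    F_i = -kB*T*ln(p_i), shifts so the global minimum is zero, and attaches
    per-bin 95% CIs from a seeded bootstrap over samples.  Unpopulated bins
    are NaN and flagged.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("empty sample set")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if weights is not None:
        weights = np.asarray(weights, dtype=float)
        if weights.sum() <= 0:
            raise ValueError("all-zero weights")
    lo = np.floor(samples.min() / bin_width) * bin_width
    hi = np.ceil(samples.max() / bin_width) * bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    if edges.size < 2:
        edges = np.array([lo, lo + bin_width])
    centers = 0.5 * (edges[:-1] + edges[1:])
    kbt = KB_KJ_PER_MOL_K * temperature_k

    def _profile(s: np.ndarray, w: np.ndarray | None) -> np.ndarray:
        counts, _ = np.histogram(s, bins=edges, weights=w)
        total = counts.sum()
        with np.errstate(divide="ignore"):
            F = -kbt * np.log(counts / total)
        F[~np.isfinite(F)] = np.nan
        return F - np.nanmin(F)

    F = _profile(samples, weights)
    populated = np.isfinite(F)

    rng = np.random.default_rng(seed)
    boot = np.full((bootstrap_b, centers.size), np.nan)
    for b in range(bootstrap_b):
        idx = rng.integers(0, samples.size, samples.size)
        boot[b] = _profile(samples[idx], None if weights is None else weights[idx])
    ci95 = np.full(centers.size, np.nan)
    for i in np.nonzero(populated)[0]:
        col = boot[:, i]
        col = col[np.isfinite(col)]
        if col.size:
            qlo, qhi = np.percentile(col, [2.5, 97.5])
            ci95[i] = (qhi - qlo) / 2.0
    return FESProfile(
        bin_centers=centers, free_energy=F, ci95=ci95,
        populated=populated, temperature_k=temperature_k,
    )


@dataclass
class BasinReport:
    """Locations and energetics of the (up to two) lowest free-energy basins."""

    minima_positions: list[float]
    minima_energies: list[float]
    delta_f: float | None
    barrier: float | None
    single_basin: bool


def basin_analysis(profile: FESProfile, min_prominence: float = 0.5) -> BasinReport:
    """Locate basins on a free-energy profile and report their gap and barrier.

    Basins are local minima of F over populated bins; the report gives the
    free-energy difference between the two lowest basins (second minus
    global) and the barrier from the global basin to the second along the
    profile.  Non-global minima must be separated from the global basin by
    at least ``min_prominence`` kJ/mol (default 0.5, far above the Poisson
    count-noise scale of well-sampled histograms but below any gap of
    physical interest) so that statistical jitter on a basin shoulder is
    not reported as a basin.  Fewer than two minima yields a single-basin
    report rather than an error.
    """
    F = profile.free_energy
    x = profile.bin_centers
    pop = np.nonzero(profile.populated)[0]
    if pop.size == 0:
        raise ValueError("no populated bins")
    minima: list[int] = []
    for i in pop:
        # an unsampled neighbour acts as an infinite wall
        left = F[i - 1] if i > 0 and profile.populated[i - 1] else np.inf
        right = F[i + 1] if i < F.size - 1 and profile.populated[i + 1] else np.inf
        if F[i] < left and F[i] <= right:
            minima.append(i)
    if min_prominence > 0 and len(minima) > 1:
        glob = min(minima, key=lambda i: F[i])
        kept = [glob]
        for i in minima:
            if i == glob:
                continue
            # prominence = barrier separating this minimum from the global
            # one; an unsampled stretch on the path separates them by more
            # than anything observed
            lo_p, hi_p = min(i, glob), max(i, glob)
            if not np.all(profile.populated[lo_p: hi_p + 1]):
                kept.append(i)
            elif np.max(F[lo_p: hi_p + 1]) - F[i] >= min_prominence:
                kept.append(i)
        minima = sorted(kept)
    if len(minima) < 2:
        i0 = minima[0] if minima else pop[np.nanargmin(F[pop])]
        return BasinReport(
            minima_positions=[float(x[i0])], minima_energies=[float(F[i0])],
            delta_f=None, barrier=None, single_basin=True,
        )
    order = sorted(minima, key=lambda i: F[i])
    g, s = order[0], order[1]
    lo, hi = min(g, s), max(g, s)
    seg = F[lo: hi + 1]
    if np.all(profile.populated[lo: hi + 1]):
        barrier = float(np.max(seg) - F[g])
    else:
        # the saddle region was never sampled: the barrier exceeds anything
        # observed and is reported as unresolved
        barrier = float("nan")
    return BasinReport(
        minima_positions=[float(x[g]), float(x[s])],
        minima_energies=[float(F[g]), float(F[s])],
        delta_f=float(F[s] - F[g]),
        barrier=barrier,
        single_basin=False,
    )


def cluster_medoids(
    matrix: np.ndarray, k: int, n_restarts: int = 10, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray, float]:
    """Seeded k-medoids partition of a precomputed distance matrix.

    Alternating assignment / medoid-update with ``n_restarts`` random
    initializations, keeping the best total within-cluster distance.
    Returns (assignments, medoid indices, median within-cluster pairwise
    distance).
    """
    D = np.asarray(matrix, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T):
        raise ValueError("matrix must be square and symmetric")
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside 1..{n}")
    rng = np.random.default_rng(seed)

    best_cost = np.inf
    best_medoids = None
    best_assign = None
    for _ in range(n_restarts):
        medoids = rng.choice(n, size=k, replace=False)
        for _ in range(100):
            assign = np.argmin(D[:, medoids], axis=1)
            new_medoids = medoids.copy()
            for c in range(k):
                members = np.nonzero(assign == c)[0]
                if members.size == 0:
                    continue
                within = D[np.ix_(members, members)].sum(axis=1)
                new_medoids[c] = members[np.argmin(within)]
            if np.array_equal(np.sort(new_medoids), np.sort(medoids)):
                break
            medoids = new_medoids
        assign = np.argmin(D[:, medoids], axis=1)
        cost = D[np.arange(n), medoids[assign]].sum()
        if cost < best_cost:
            best_cost, best_medoids, best_assign = cost, medoids.copy(), assign.copy()

    within_pairs: list[float] = []
    for c in range(k):
        members = np.nonzero(best_assign == c)[0]
        for ii in range(members.size):
            for jj in range(ii + 1, members.size):
                within_pairs.append(D[members[ii], members[jj]])
    median_within = float(np.median(within_pairs)) if within_pairs else 0.0
    return best_assign, best_medoids, median_within


# ---------------------------------------------------------------------------
# PDB I/O (CA atoms, chain A, MODEL/ENDMDL records)

def read_multimodel_pdb(path, weights_tsv=None) -> Ensemble:
    """Read a multi-model PDB as a CA-only ensemble (chain A).

    ``weights_tsv`` optionally supplies statistical weights as a
    tab-delimited (model_index, weight) table.
    """
    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure(model=None)
    mask = (stack.atom_name == "CA") & (stack.chain_id == "A")
    sub = stack[:, mask]
    conformations = [
        Conformation(
            residue_numbers=sub.res_id,
            ca_coords=sub.coord[m],
            label=f"model_{m + 1}",
        )
        for m in range(sub.stack_depth())
    ]
    weights = None
    if weights_tsv is not None:
        wdf = pd.read_csv(weights_tsv, sep="\t")
        weights = (
            wdf.sort_values("model_index")["weight"].to_numpy(dtype=float)
        )
    return Ensemble(conformations=conformations, weights=weights)


def write_multimodel_pdb(ensemble: Ensemble, path) -> None:
    """Write a CA-only ensemble as a multi-model PDB (chain A, GLY CA)."""
    n_res = ensemble.conformations[0].residue_numbers.size
    template = struc.AtomArray(n_res)
    template.chain_id[:] = "A"
    template.res_id[:] = ensemble.conformations[0].residue_numbers
    template.res_name[:] = "GLY"
    template.atom_name[:] = "CA"
    template.element[:] = "C"
    stack = struc.stack([template] * len(ensemble))
    stack.coord = np.array([c.ca_coords for c in ensemble.conformations])
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))
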