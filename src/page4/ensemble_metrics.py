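"""Order metrics for disordered-protein conformational ensembles.

Operates on Cα-level ensembles (conformers × residues × xyz, in Å) and
computes the observables used to compare the PAGE4 phospho-forms: radius
of gyration and its free-energy profile F = -kT log P, inter-residue
distance distributions, ensemble contact maps, contact-based principal
component analysis, and a geometric turn propensity.

Residue numbering is 1-based throughout, matching the 102-residue PAGE4
sequence annotation: N-motif 4–12, central acidic region 43–62,
transiently helical region 65–73, C-motif 82–95.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PAGE4_LENGTH", "REGIONS", "Ensemble", "ContactMap", "PCAResult",
    "radius_of_gyration", "free_energy_profile",
    "pairwise_distance_distribution", "contact_map", "contact_pca",
    "turn_propensity", "FRET_PAIRS",
]

PAGE4_LENGTH = 102

#: functional segments of PAGE4 (1-based, inclusive)
REGIONS = {
    "n_motif": (4, 12),
    "central_acidic": (43, 62),
    "transient_helix": (65, 73),
    "c_motif": (82, 95),
}

#: residue pairs probed in single-molecule FRET: one in each chain half
FRET_PAIRS = ((18, 63), (63, 102))

#: defaults for the contact definition (Cα–Cα, coarse-grained convention)
CONTACT_CUTOFF_A = 9.5
MIN_SEQ_SEP = 3

#: geometric turn criterion: residues i and i+3 close in space, with the
#: intervening virtual-bond angles bent away from collinear
TURN_DISTANCE_A = 7.0
TURN_MAX_ANGLE_DEG = 150.0


class EnsembleError(ValueError):
    """Invalid ensemble input."""


@dataclass
class Ensemble:
    """Cα coordinates of N conformers of one chain, shape (N, L, 3) in Å."""

    coords: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise EnsembleError("coords must have shape (n_conformers, L, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise EnsembleError("coordinates contain NaN/inf")

    @property
    def n_conformers(self) -> int:
        return self.coords.shape[0]

    @property
    def chain_length(self) -> int:
        return self.coords.shape[1]

    def residue(self, i: int) -> np.ndarray:
        """Coordinates of residue ``i`` (1-based) across conformers."""
        if not 1 <= i <= self.chain_length:
            raise EnsembleError(f"residue {i} outside 1..{self.chain_length}")
        return self.coords[:, i - 1, :]


@dataclass
class ContactMap:
    """Symmetric L×L contact-probability matrix."""

    matrix: np.ndarray
    cutoff: float = CONTACT_CUTOFF_A
    min_seq_sep: int = MIN_SEQ_SEP

    def block_mean(self, rows: tuple[int, int], cols: tuple[int, int]) -> float:
        """Mean contact probability over a region × region block (1-based,
        inclusive bounds)."""
        r0, r1 = rows
        c0, c1 = cols
        return float(self.matrix[r0 - 1:r1, c0 - 1:c1].mean())


@dataclass
class PCAResult:
    """Principal modes over retained contact-pair space."""

    modes: np.ndarray         # (n_modes, n_pairs), orthonormal rows
    eigenvalues: np.ndarray   # descending, non-negative
    pair_index: np.ndarray    # (n_pairs, 2) of 1-based (i, j), i < j

    def mode_coefficient(self, mode: int, i: int, j: int) -> float:
        """Loading of pair (i, j) on ``mode`` (0-based mode index)."""
        if i > j:
            i, j = j, i
        hit = np.nonzero((self.pair_index[:, 0] == i)
                         & (self.pair_index[:, 1] == j))[0]
        if hit.size == 0:
            raise KeyError(f"pair ({i}, {j}) not retained")
        return float(self.modes[mode, hit[0]])


def radius_of_gyration(conformer: np.ndarray) -> float:
    """Unweighted Rg: RMS distance of residues from their centroid (Å)."""
    xyz = np.asarray(conformer, dtype=float)
    if xyz.ndim != 2 or xyz.shape[0] < 2 or xyz.shape[1] != 3:
        raise EnsembleError("conformer must be (n_residues >= 2, 3)")
    d = xyz - xyz.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))


def ensemble_rg(ensemble: Ensemble) -> np.ndarray:
    """Per-conformer radius of gyration, vectorised."""
    d = ensemble.coords - ensemble.coords.mean(axis=1, keepdims=True)
    return np.sqrt(np.mean(np.sum(d * d, axis=2), axis=1))


def free_energy_profile(samples: np.ndarray, n_bins: int = 30,
                        kT: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Free-energy profile F = -kT log P from scalar samples.

    Returns bin centers and F shifted so its minimum is 0; bins with no
    samples get ``nan`` (never ±inf). A degenerate all-identical input
    collapses to a single occupied bin with a warning.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 100:
        raise EnsembleError("need at least 100 samples for a profile")
    if n_bins < 5:
        raise EnsembleError("need at least 5 bins")
    if np.ptp(x) == 0.0:
        warnings.warn("all samples identical; degenerate single-bin profile")
        return np.array([x[0]]), np.array([0.0])
    counts, edges = np.histogram(x, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    p = counts / counts.sum()
    F = np.full(n_bins, np.nan)
    occ = p > 0
    F[occ] = -kT * np.log(p[occ])
    F[occ] -= np.nanmin(F[occ])
    return centers, F


def pairwise_distance_distribution(ensemble: Ensemble, i: int, j: int,
                                   n_bins: int = 40
                                   ) -> tuple[np.ndarray, np.ndarray]:
    """Normalized histogram of the residue i–j Cα distance over conformers.

    Returns (bin centers, probability per bin); probabilities sum to 1.
    """
    if i == j:
        raise EnsembleError("need two distinct residues")
    d = pair_distances(ensemble, i, j)
    lo, hi = d.min(), d.max()
    if hi == lo:
        hi = lo + 1e-9
    counts, edges = np.histogram(d, bins=n_bins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, counts / counts.sum()


def pair_distances(ensemble: Ensemble, i: int, j: int) -> np.ndarray:
    """Per-conformer Cα distance between residues i and j (1-based)."""
    return np.linalg.norm(ensemble.residue(i) - ensemble.residue(j), axis=1)


def _contact_tensor(ensemble: Ensemble, cutoff: float, min_seq_sep: int
                    ) -> np.ndarray:
    """Boolean (n_conformers, L, L) contact tensor with the |i-j| mask."""
    diff = ensemble.coords[:, :, None, :] - ensemble.coords[:, None, :, :]
    dist = np.linalg.norm(diff, axis=3)
    contacts = dist <= cutoff
    L = ensemble.chain_length
    ii, jj = np.meshgrid(np.arange(L), np.arange(L), indexing="ij")
    contacts &= np.abs(ii - jj) >= min_seq_sep
    return contacts


def contact_map(ensemble: Ensemble, cutoff: float = CONTACT_CUTOFF_A,
                min_seq_sep: int = MIN_SEQ_SEP) -> ContactMap:
    """Ensemble contact-probability map.

    Entry (i, j) is the fraction of conformers in which residues i and j
    lie within ``cutoff`` Å; pairs closer than ``min_seq_sep`` in
    sequence are masked to zero.
    """
    contacts = _contact_tensor(ensemble, cutoff, min_seq_sep)
    return ContactMap(matrix=contacts.mean(axis=0), cutoff=cutoff,
                      min_seq_sep=min_seq_sep)


def contact_pca(ensemble: Ensemble, cutoff: float = CONTACT_CUTOFF_A,
                min_seq_sep: int = MIN_SEQ_SEP, n_modes: int = 2) -> PCAResult:
    """PCA of per-conformer binary contact vectors.

    Each conformer is encoded as a 0/1 vector over the retained residue
    pairs (upper triangle, |i-j| >= min_seq_sep); the principal modes are
    the eigenvectors of the population covariance of those vectors.
    Anti-correlated loop formation shows up as opposite-sign loadings of
    the two loops' pairs on the same mode.

    Sign convention: each mode is flipped so its largest-magnitude
    coefficient is positive.
    """
    if ensemble.n_conformers < n_modes + 1:
        raise EnsembleError("need at least n_modes + 1 conformers")
    contacts = _contact_tensor(ensemble, cutoff, min_seq_sep)
    L = ensemble.chain_length
    iu, ju = np.triu_indices(L, k=min_seq_sep)
    X = contacts[:, iu, ju].astype(float)          # (N, n_pairs)
    Xc = X - X.mean(axis=0)
    if not np.any(Xc):
        raise EnsembleError("degenerate covariance: no contact varies "
                            "across conformers")
    # economy SVD of the centered data equals covariance eigendecomposition
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigvals = s ** 2 / X.shape[0]                  # population covariance
    modes = Vt[:n_modes]
    flip = np.sign(modes[np.arange(n_modes),
                         np.argmax(np.abs(modes), axis=1)])
    modes = modes * flip[:, None]
    pair_index = np.column_stack([iu + 1, ju + 1])
    return PCAResult(modes=modes, eigenvalues=eigvals[:n_modes],
                     pair_index=pair_index)


def turn_propensity(ensemble: Ensemble) -> np.ndarray:
    """Per-residue fraction of conformers in a turn-like local geometry.

    Residue i is turn-like in a conformer iff the Cα(i)–Cα(i+3) distance
    is under 7 Å and neither intervening virtual-bond angle exceeds 150°
    (excluding near-collinear stretches). This geometric criterion is the
    package's secondary-structure proxy for Cα-only ensembles. The first
    and last three residues are reported as ``nan`` (missing).
    """
    L = ensemble.chain_length
    if L < 4:
        raise EnsembleError("chain too short for turn analysis")
    xyz = ensemble.coords
    out = np.full(L, np.nan)
    # virtual-bond angle at interior residue k (0-based): angle between
    # (r[k-1]-r[k]) and (r[k+1]-r[k]); 180 deg = straight
    v1 = xyz[:, :-2, :] - xyz[:, 1:-1, :]
    v2 = xyz[:, 2:, :] - xyz[:, 1:-1, :]
    cosang = np.sum(v1 * v2, axis=2) / (
        np.linalg.norm(v1, axis=2) * np.linalg.norm(v2, axis=2))
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))  # (N, L-2)
    for k in range(3, L - 3):      # 0-based start residue of the i..i+3 span
        d = np.linalg.norm(xyz[:, k + 3, :] - xyz[:, k, :], axis=1)
        bent = np.maximum(ang[:, k], ang[:, k + 1]) < TURN_MAX_ANGLE_DEG
        out[k] = np.mean((d < TURN_DISTANCE_A) & bent)
    return out


def region_mean(values: np.ndarray, region: tuple[int, int]) -> float:
    """Mean of a per-residue array over a 1-based inclusive region."""
    lo, hi = region
    return float(np.nanmean(values[lo - 1:hi]))
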