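"""Synthetic Cα ensembles emulating the PAGE4 phospho-form signatures.

This generator produces 102-residue Cα chains by constrained self-avoiding
random walks. It is an emulator: conformers are i.i.d. draws with no
energetics or kinetics, built only to carry the statistical structure the
ensemble metrics probe —

* WT: frequent N-terminal loop (N-motif 4–12 against the central acidic
  region 43–62), no C-terminal loop;
* HIPK1: N- and C-terminal loops (C-motif 82–95 against the central
  region) formed mutually exclusively, giving anti-correlated loop modes;
* CLK2: no loops and an increased persistence ("expansion") producing a
  globally swollen chain, with the N-terminal half expanding most
  strongly relative to the loop-compacted WT baseline.

Loop restraints (region-centroid distance ≤ 9 Å) are enforced by
rejection sampling of the relevant chain segment, so restrained and
unrestrained conformers share the same local chain statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ensemble_metrics import PAGE4_LENGTH, REGIONS, Ensemble

__all__ = ["EnsemblePreset", "GenerationError", "generate_conformer",
           "generate_ensemble", "default_presets"]

BOND_LENGTH_A = 3.8        # virtual Cα–Cα bond
EXCLUSION_A = 3.0          # minimum non-bonded Cα–Cα distance
LOOP_RESTRAINT_A = 9.0     # max region-centroid separation for a loop
BASE_STIFFNESS = 0.9       # persistence weight at expansion = 1
MAX_ATTEMPTS = 10_000      # rejection budget per restrained segment


class GenerationError(RuntimeError):
    """A loop restraint could not be satisfied within the attempt budget."""


@dataclass(frozen=True)
class EnsemblePreset:
    """Generation parameters for one phospho-form emulation."""

    name: str
    p_n_loop: float = 0.0     # fraction of conformers with the N loop
    p_c_loop: float = 0.0     # fraction with the C loop
    exclusivity: bool = False  # at most one loop restraint per conformer
    expansion: float = 1.0    # >= 1; scales chain persistence
    seed: int = 42

    def __post_init__(self):
        if not (0.0 <= self.p_n_loop <= 1.0 and 0.0 <= self.p_c_loop <= 1.0):
            raise ValueError("loop probabilities must lie in [0, 1]")
        if self.exclusivity and self.p_n_loop + self.p_c_loop > 1.0 + 1e-12:
            raise ValueError("exclusive loop probabilities must sum to <= 1")
        if self.expansion < 1.0:
            raise ValueError("expansion must be >= 1")


def default_presets() -> dict[str, EnsemblePreset]:
    """The three phospho-form presets (emulation knobs, not measured values)."""
    return {
        "WT": EnsemblePreset("WT", p_n_loop=0.6),
        "HIPK1": EnsemblePreset("HIPK1", p_n_loop=0.45, p_c_loop=0.45,
                                exclusivity=True),
        "CLK2": EnsemblePreset("CLK2", expansion=1.8),
    }


def _grow_segment(buf: np.ndarray, start: int, stop: int, stiffness: float,
                  rng: np.random.Generator, max_step_tries: int = 40) -> bool:
    """Grow residues ``start..stop-1`` (0-based) of ``buf`` in place by a
    persistent self-avoiding walk; residues before ``start`` are fixed.

    Returns False if the walk trapped itself.
    """
    i = start
    if i == 0:
        buf[0] = 0.0            # the chain's first residue sits at the origin
        i = 1
    prev_dir = None
    if i >= 2:
        prev_dir = (buf[i - 1] - buf[i - 2]) / BOND_LENGTH_A
    excl2 = EXCLUSION_A ** 2
    while i < stop:
        prev = buf[i - 1]
        for _ in range(max_step_tries):
            eta = rng.standard_normal(3)
            d = eta if prev_dir is None else stiffness * prev_dir + eta
            d /= np.linalg.norm(d)
            pos = prev + BOND_LENGTH_A * d
            # non-bonded clash check (immediate predecessor is bonded)
            if i >= 2:
                delta = buf[:i - 1] - pos
                if np.min(np.einsum("ij,ij->i", delta, delta)) < excl2:
                    continue
            buf[i] = pos
            prev_dir = d
            i += 1
            break
        else:
            return False
    return True


def _centroid(coords: np.ndarray, region: tuple[int, int]) -> np.ndarray:
    lo, hi = region
    return coords[lo - 1:hi].mean(axis=0)


def generate_conformer(preset: EnsemblePreset, rng: np.random.Generator,
                       chain_length: int = PAGE4_LENGTH) -> np.ndarray:
    """Draw one conformer (chain_length, 3) honoring the preset's loops.

    The chain grows in two stages — residues 1..62 then 63..end — so each
    loop restraint can be enforced by rejecting and regrowing only the
    segment it involves.
    """
    stiffness = BASE_STIFFNESS * preset.expansion
    want_n, want_c = _draw_loops(preset, rng)
    split = min(REGIONS["central_acidic"][1], chain_length)   # residue 62
    buf = np.empty((chain_length, 3))

    for _ in range(MAX_ATTEMPTS):
        if not _grow_segment(buf, 0, split, stiffness, rng):
            continue
        if want_n:
            d = np.linalg.norm(_centroid(buf, REGIONS["n_motif"])
                               - _centroid(buf, REGIONS["central_acidic"]))
            if d > LOOP_RESTRAINT_A:
                continue
        break
    else:
        raise GenerationError("N-loop restraint unsatisfied within budget")

    if chain_length <= split:
        return buf.copy()

    for _ in range(MAX_ATTEMPTS):
        if not _grow_segment(buf, split, chain_length, stiffness, rng):
            continue
        if want_c:
            d = np.linalg.norm(_centroid(buf, REGIONS["c_motif"])
                               - _centroid(buf, REGIONS["central_acidic"]))
            if d > LOOP_RESTRAINT_A:
                continue
        return buf.copy()
    raise GenerationError("C-loop restraint unsatisfied within budget")


def _draw_loops(preset: EnsemblePreset, rng: np.random.Generator
                ) -> tuple[bool, bool]:
    if preset.exclusivity:
        u = rng.random()
        return u < preset.p_n_loop, preset.p_n_loop <= u < preset.p_n_loop + preset.p_c_loop
    return (bool(rng.random() < preset.p_n_loop),
            bool(rng.random() < preset.p_c_loop))


def generate_ensemble(preset: EnsemblePreset, n_conformers: int,
                      seed: int | None = None,
                      chain_length: int = PAGE4_LENGTH) -> Ensemble:
    """Generate an i.i.d. ensemble; deterministic given the seed."""
    if n_conformers < 1:
        raise ValueError("n_conformers must be >= 1")
    rng = np.random.default_rng(preset.seed if seed is None else seed)
    coords = np.stack([generate_conformer(preset, rng, chain_length)
                       for _ in range(n_conformers)])
    return Ensemble(coords=coords)
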