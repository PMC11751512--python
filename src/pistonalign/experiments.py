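"""End-to-end simulation experiments: power, type-I error and parameter recovery.

These drive the full pipeline (generate -> crossing selection -> ellipse fit ->
shape-relative scoring -> binning -> frequency tables -> tests) on synthetic
monolayers where the truth is known, providing the package's evidence that the
statistical procedures behave as designed: nominal false-positive rate when no
alignment is simulated, high power at a strong alignment signal, and a moment
estimator of the aligned fraction that recovers the simulated value.
"""

from __future__ import annotations

import math
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .geometry import ShapeKind
from .scoring import BIN_ORDER, AngleBin, UNIFORM_BIN_FRACTIONS, score_region
from .simulate import SyntheticConfig, _sample_orientation_labelled, generate_cell, generate_monolayer
from .stats import FrequencyTable, chi_square_test, frequency_table

__all__ = [
    "axial_von_mises_bin_masses",
    "mixture_bin_masses",
    "estimate_align_fraction",
    "generate_periphery_cells",
    "scored_pair_tables",
    "replicate_chi_square_pvalues",
]


def axial_von_mises_bin_masses(kappa: float) -> np.ndarray:
    """Bin masses of the aligned component.

    The aligned shape-relative angle is 90 + V/2 with V ~ von Mises(0, kappa) on
    the doubled-angle circle, so the mass of a relative-angle interval [lo, hi]
    is the von Mises mass of [2(lo-90), 2(hi-90)] degrees.  Returns masses in
    BIN_ORDER (radial, peripheral, oblique_near, oblique_far).
    """
    vm = sps.vonmises(kappa)

    def mass(lo_deg: float, hi_deg: float) -> float:
        lo = math.radians(2.0 * (lo_deg - 90.0))
        hi = math.radians(2.0 * (hi_deg - 90.0))
        return float(vm.cdf(hi) - vm.cdf(lo))

    radial = mass(70.0, 110.0)
    oblique_near = mass(50.0, 70.0) + mass(110.0, 130.0)
    oblique_far = mass(20.0, 50.0) + mass(130.0, 160.0)
    peripheral = 1.0 - radial - oblique_near - oblique_far
    return np.array([radial, peripheral, oblique_near, oblique_far])


def mixture_bin_masses(align_fraction: float, kappa: float) -> np.ndarray:
    """Expected bin probabilities for periphery-zone cells under the mixture model."""
    uniform = np.array([UNIFORM_BIN_FRACTIONS[b] for b in BIN_ORDER])
    return align_fraction * axial_von_mises_bin_masses(kappa) + (1.0 - align_fraction) * uniform


def estimate_align_fraction(table: FrequencyTable, kappa: float) -> float:
    """Moment estimate of the aligned fraction from the radial-bin excess.

    Inverts ``f_radial = pi * m_radial(kappa) + (1 - pi) * 40/180`` using the
    observed radial fraction; requires the concentration ``kappa`` of the aligned
    component (known in simulation studies).
    """
    m_radial = axial_von_mises_bin_masses(kappa)[0]
    baseline = UNIFORM_BIN_FRACTIONS[AngleBin.RADIAL]
    f_radial = table.counts[0] / table.n
    return (f_radial - baseline) / (m_radial - baseline)


def generate_periphery_cells(
    config: SyntheticConfig,
    n: int,
    rng: np.random.Generator,
    region: str = "piston",
    day: int = 0,
) -> Tuple[list, pd.DataFrame]:
    """Generate ``n`` cells centred on the periphery curve itself.

    A focused harness for distributional checks: every cell crosses the
    periphery by construction, so the scored sample size equals ``n`` (minus any
    isotropic exclusions).  No packing constraint is applied.
    """
    shape = config.shape
    outlines, rows = [], []
    uniform_only = region == "control"
    if shape.kind is ShapeKind.CIRCLE:
        u = rng.uniform(0.0, 2.0 * np.pi, size=n)
        cx, cy = shape.centroid
        pts = np.column_stack([cx + shape.radius * np.cos(u), cy + shape.radius * np.sin(u)])
    else:
        v = shape.vertices()
        edges = np.roll(v, -1, axis=0) - v
        lengths = np.sqrt((edges ** 2).sum(axis=1))
        which = rng.choice(len(v), size=n, p=lengths / lengths.sum())
        frac = rng.uniform(0.0, 1.0, size=n)
        pts = v[which] + frac[:, None] * edges[which]
    for i, (x, y) in enumerate(pts):
        alpha, in_zone, latent = _sample_orientation_labelled((x, y), config, rng, uniform_only)
        cell_id = f"{region}-periph-{i:04d}"
        outlines.append(generate_cell((x, y), alpha, config, rng, cell_id, day, region))
        rows.append((cell_id, x, y, alpha, in_zone, latent))
    truth = pd.DataFrame(rows, columns=["cell_id", "x", "y", "true_alpha", "in_zone", "latent"])
    return outlines, truth


def scored_pair_tables(
    config: SyntheticConfig,
    day: int = 0,
    min_aspect: Optional[float] = None,
) -> Tuple[FrequencyTable, FrequencyTable]:
    """Generate a full piston field and a full control field, score both against
    the config's shape, and return the two frequency tables."""
    ft = []
    for region in ("piston", "control"):
        outlines, _ = generate_monolayer(config, day=day, region=region)
        result = score_region(config.shape, outlines, min_aspect=min_aspect)
        ft.append(frequency_table(result.records, group_label=region, day=day))
    return ft[0], ft[1]


def periphery_pair_tables(
    config: SyntheticConfig,
    cells_per_region: int,
    rng: np.random.Generator,
) -> Tuple[FrequencyTable, FrequencyTable]:
    """Frequency tables for a biased piston group and a uniform control group of
    periphery cells, both scored through the standard pipeline."""
    ft = []
    for region in ("piston", "control"):
        outlines, _ = generate_periphery_cells(config, cells_per_region, rng, region=region)
        result = score_region(config.shape, outlines)
        ft.append(frequency_table(result.records, group_label=region, day=0))
    return ft[0], ft[1]


def replicate_chi_square_pvalues(
    config: SyntheticConfig,
    n_replicates: int,
    cells_per_region: int = 100,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Repeat the piston-vs-control chi-square comparison over seeded replicates.

    Each replicate generates ``cells_per_region`` periphery cells per group (the
    piston group with the config's alignment mixture, the control group with
    uniform orientations), scores them through the full selection/fit/binning
    pipeline, and tests the two frequency tables.  Returns one row per replicate
    with the p-value and both scored sample sizes.
    """
    rows = []
    for i in range(n_replicates):
        rng = np.random.default_rng(np.random.SeedSequence([int(base_seed), i]))
        ft_piston, ft_control = periphery_pair_tables(config, cells_per_region, rng)
        res = chi_square_test(ft_piston, ft_control)
        rows.append((i, res.p_two_sided, ft_piston.n, ft_control.n))
    return pd.DataFrame(rows, columns=["replicate", "p", "n_piston", "n_control"])
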