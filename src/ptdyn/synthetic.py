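"""Synthetic single-cell expression with a known latent pseudotime.

Each cell carries a latent progression coordinate t ~ Uniform(0, 1).
Gene modules follow fixed temporal shape functions f: [0,1] -> [0,1]
(decreasing stromal sigmoid, delayed proliferation ramp, saturating
oxphos, late-rising glycolysis, an antagonistic bipolar pair, linear
chromatin-state trends), so every downstream stage — filtering,
normalization, signature scoring, pseudotime inference, smoothing,
association testing and trajectory typology — can be validated against
ground truth.

Expression is built on the log2 scale as ``baseline + amplitude * f(t)``
plus Gaussian noise, converted to an FPKM-like scale via ``2**x - 1``
truncated at zero, with Bernoulli dropout on non-housekeeping entries.
Housekeeping genes (ACTB, GAPDH) are constitutively high except in a
configurable fraction of "failed" cells whose housekeeping rows are
zeroed, emulating cells that fail quality filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GeneSetCollection, validate_matrix

HOUSEKEEPING_GENES = ("ACTB", "GAPDH")

#: log2-scale expression level of an inactive (baseline) gene.
DEFAULT_BASELINE = 3.0
#: log2-scale expression level of housekeeping genes.
HOUSEKEEPING_BASELINE = 8.0

SHAPE_NAMES = (
    "decreasing_sigmoid",
    "delayed_ramp",
    "saturating",
    "late_rise",
    "bipolar_high",
    "bipolar_low",
    "linear_up",
    "linear_down",
    "constant",
)


def shape_function(shape: str, onset: float, steepness: float):
    """Return the temporal activity function f: [0,1] -> [0,1] for a shape.

    ``onset`` locates half-activation (or ramp start) in pseudotime;
    ``steepness`` controls how sharply sigmoidal / saturating shapes turn.
    """
    if shape == "decreasing_sigmoid":
        return lambda t: 1.0 / (1.0 + np.exp(steepness * (np.asarray(t) - onset)))
    if shape == "delayed_ramp" or shape == "late_rise":
        # late_rise is the same ramp, conventionally used with a larger onset
        def ramp(t):
            t = np.asarray(t, dtype=float)
            return np.where(t < onset, 0.0, (t - onset) / (1.0 - onset))
        return ramp
    if shape == "saturating":
        return lambda t: 1.0 - np.exp(-steepness * np.asarray(t))
    if shape == "bipolar_high":
        return lambda t: 1.0 / (1.0 + np.exp(-steepness * (np.asarray(t) - onset)))
    if shape == "bipolar_low":
        return lambda t: 1.0 - 1.0 / (1.0 + np.exp(-steepness * (np.asarray(t) - onset)))
    if shape == "linear_up":
        return lambda t: np.asarray(t, dtype=float)
    if shape == "linear_down":
        return lambda t: 1.0 - np.asarray(t, dtype=float)
    if shape == "constant":
        return lambda t: np.ones_like(np.asarray(t, dtype=float))
    raise ValueError(f"unknown shape {shape!r}; choose one of {SHAPE_NAMES}")


@dataclass
class ModuleSpec:
    """One temporally patterned gene module.

    Parameters
    ----------
    name
        Module label; also names the derived gene set.
    shape
        One of :data:`SHAPE_NAMES`.
    n_genes
        Number of genes carrying the module's profile (>= 1).
    amplitude
        Dynamic range in log2-expression units (>= 0).
    onset
        Pseudotime of half-activation / ramp start, in [0, 1].
    steepness
        Sharpness of sigmoidal and saturating shapes (> 0).
    """

    name: str
    shape: str
    n_genes: int = 40
    amplitude: float = 2.0
    onset: float = 0.5
    steepness: float = 8.0

    def __post_init__(self) -> None:
        if self.shape not in SHAPE_NAMES:
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if not 0.0 <= self.onset <= 1.0:
            raise ValueError("onset must lie in [0, 1]")
        if self.steepness <= 0:
            raise ValueError("steepness must be > 0")

    def activity(self, t) -> np.ndarray:
        """Evaluate the module's shape function at pseudotime(s) t."""
        return np.asarray(shape_function(self.shape, self.onset, self.steepness)(t))


@dataclass
class SyntheticDataset:
    """An expression matrix bundled with its generating ground truth."""

    matrix: pd.DataFrame
    true_pt: pd.Series
    module_map: dict[str, str]
    gmt: GeneSetCollection
    params: dict

    @property
    def cell_ids(self) -> list[str]:
        return list(self.matrix.columns)


def generate_dataset(
    n_cells: int,
    modules: list[ModuleSpec],
    n_background: int = 400,
    noise_sd: float = 0.5,
    dropout_rate: float = 0.2,
    frac_failed_cells: float = 0.0,
    seed: int = 0,
    baseline: float = DEFAULT_BASELINE,
    housekeeping_baseline: float = HOUSEKEEPING_BASELINE,
) -> SyntheticDataset:
    """Simulate an FPKM-like genes x cells matrix with known pseudotime.

    Parameters
    ----------
    n_cells
        Number of cells (>= 10; pseudotime on fewer cells is meaningless).
    modules
        Non-empty list of :class:`ModuleSpec`.
    n_background
        Genes with baseline-plus-noise expression and no temporal pattern.
    noise_sd
        SD of log2-scale Gaussian noise (>= 0).
    dropout_rate
        Probability of zeroing each non-housekeeping entry, in [0, 1).
    frac_failed_cells
        Fraction of cells whose housekeeping genes are zeroed, in [0, 1).
    seed
        Seeds all randomness; identical seed gives an identical dataset.

    Returns
    -------
    SyntheticDataset
        Matrix plus true pseudotime, gene -> module map, a derived GMT
        collection (one set per module) and the full parameter record.
    """
    if n_cells < 10:
        raise ValueError("n_cells must be >= 10: pseudotime on fewer cells is meaningless")
    if not modules:
        raise ValueError("modules must be non-empty")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if not 0.0 <= dropout_rate < 1.0:
        raise ValueError("dropout_rate must lie in [0, 1)")
    if not 0.0 <= frac_failed_cells < 1.0:
        raise ValueError("frac_failed_cells must lie in [0, 1)")
    if n_background < 0:
        raise ValueError("n_background must be >= 0")

    rng = np.random.default_rng(seed)
    t = rng.uniform(0.0, 1.0, size=n_cells)
    cell_ids = [f"cell_{i:04d}" for i in range(n_cells)]

    gene_ids: list[str] = []
    module_map: dict[str, str] = {}
    rows: list[np.ndarray] = []

    for module in modules:
        profile = baseline + module.amplitude * module.activity(t)
        for g in range(module.n_genes):
            gene = f"{module.name}_g{g:03d}"
            gene_ids.append(gene)
            module_map[gene] = module.name
            rows.append(profile.copy())
    for g in range(n_background):
        gene_ids.append(f"BG_{g:04d}")
        rows.append(np.full(n_cells, baseline))
    for hk in HOUSEKEEPING_GENES:
        gene_ids.append(hk)
        rows.append(np.full(n_cells, housekeeping_baseline))

    if len(set(gene_ids)) != len(gene_ids):
        raise ValueError("generated gene names collide; rename modules")

    log2_expr = np.vstack(rows)
    if noise_sd > 0:
        log2_expr = log2_expr + rng.normal(0.0, noise_sd, size=log2_expr.shape)

    fpkm = np.clip(np.exp2(log2_expr) - 1.0, 0.0, None)

    n_hk = len(HOUSEKEEPING_GENES)
    if dropout_rate > 0:
        mask = rng.random(size=(fpkm.shape[0] - n_hk, n_cells)) < dropout_rate
        fpkm[:-n_hk][mask] = 0.0

    n_failed = int(round(frac_failed_cells * n_cells))
    failed = rng.choice(n_cells, size=n_failed, replace=False) if n_failed else []
    fpkm[-n_hk:, failed] = 0.0

    matrix = pd.DataFrame(fpkm, index=gene_ids, columns=cell_ids)
    validate_matrix(matrix)

    gmt = GeneSetCollection(
        sets={m.name: [g for g in gene_ids if module_map.get(g) == m.name]
              for m in modules},
        source="synthetic module map",
        descriptions={m.name: f"synthetic {m.shape} module" for m in modules},
    )
    params = {
        "n_cells": n_cells,
        "modules": [vars(m).copy() for m in modules],
        "n_background": n_background,
        "noise_sd": noise_sd,
        "dropout_rate": dropout_rate,
        "frac_failed_cells": frac_failed_cells,
        "seed": seed,
        "baseline": baseline,
        "housekeeping_baseline": housekeeping_baseline,
    }
    return SyntheticDataset(
        matrix=matrix,
        true_pt=pd.Series(t, index=cell_ids, name="true_pt"),
        module_map=module_map,
        gmt=gmt,
        params=params,
    )


def default_modules(mitf_high_late: bool = True) -> list[ModuleSpec]:
    """The default module panel emulating the melanoma progression programs.

    A decreasing stromal program anchors early pseudotime, a delayed
    proliferation (cell cycle) ramp anchors late pseudotime, oxphos
    saturates early, glycolysis rises late, MITF/AXL form an antagonistic
    bipolar pair, and active/poised promoter programs (TssA/TssP) trend
    linearly in opposite directions. ``mitf_high_late`` flips which member
    of the bipolar pair rises with pseudotime, mimicking cultures with
    opposite MITF/AXL polarity.
    """
    mitf_shape = "bipolar_high" if mitf_high_late else "bipolar_low"
    axl_shape = "bipolar_low" if mitf_high_late else "bipolar_high"
    return [
        ModuleSpec("stromal", "decreasing_sigmoid", onset=0.4, steepness=8.0),
        ModuleSpec("cellcycle", "delayed_ramp", onset=0.3),
        ModuleSpec("oxphos", "saturating", steepness=6.0),
        ModuleSpec("glycolysis", "late_rise", onset=0.6),
        ModuleSpec("MITF", mitf_shape, onset=0.5, steepness=8.0),
        ModuleSpec("AXL", axl_shape, onset=0.5, steepness=8.0),
        ModuleSpec("TssP", "linear_down"),
        ModuleSpec("TssA", "linear_up"),
    ]


#: (label, pre-filter cell count, failed-cell count) for the three
#: culture-sized fixtures; after housekeeping filtering the surviving
#: counts are 84, 54 and 77 cells.
CULTURE_SIZES = (
    ("wt_wt", 93, 9),
    ("braf_mut_nras_wt", 60, 6),
    ("braf_wt_nras_mut", 85, 8),
)


def culture_fixtures(seed: int = 0, noise_sd: float = 0.5,
                        dropout_rate: float = 0.2) -> dict[str, SyntheticDataset]:
    """Three culture-sized datasets processed independently downstream.

    The third culture flips MITF/AXL polarity so that biaxial MITF-vs-AXL
    trajectories from different cultures end in opposite corners
    (the divergent archetype).
    """
    fixtures: dict[str, SyntheticDataset] = {}
    seeds = np.random.SeedSequence(seed).generate_state(len(CULTURE_SIZES))
    for (label, n_cells, n_failed), sub_seed in zip(CULTURE_SIZES, seeds):
        fixtures[label] = generate_dataset(
            n_cells=n_cells,
            modules=default_modules(mitf_high_late=(label != "braf_wt_nras_mut")),
            noise_sd=noise_sd,
            dropout_rate=dropout_rate,
            frac_failed_cells=n_failed / n_cells,
            seed=int(sub_seed % (2**31)),
        )
    return fixtures
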