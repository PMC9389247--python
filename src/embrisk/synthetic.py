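"""Synthetic UMI count generator with planted pathway programs, a
discriminative gene panel, and QC outliers.

The generator emulates the statistical structure the pipeline assumes in
cultured stromal cell scRNA-seq data:

* per-gene baseline negative-binomial means drawn from a gamma prior,
  with lognormal cell library-size factors (``var = mu + mu^2/theta``);
* a small number of latent pathway-activation programs: each cell
  belongs to one program and expresses that program's gene set at a
  fold-change above baseline.  One program is the pro-embolic state and
  its gene set carries the four fibrin-clot/coagulation pathway names;
* a discriminative gene panel separating embolic (+1) from non-embolic
  (-1) cells, either shared (all panel genes shifted in every +1 cell)
  or exclusive (each +1 cell switches on a single panel gene, modeling
  cells that activate different coagulation effectors);
* mitochondrial genes with bounded cell-to-cell content variation, and
  planted QC outlier cells with inflated/deflated library sizes and
  elevated mitochondrial fraction.

Program membership is assigned by largest-remainder quota (exact counts,
then a seeded shuffle of cell order), not multinomial sampling, so
cluster-count checks are stable.  Identical scenarios (including seed)
produce bit-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CountMatrix, GeneSetCollection, write_gmt, write_mtx_dir
from .scoring import EMBOLIC_PATHWAYS

__all__ = [
    "DEFAULT_PANEL",
    "SyntheticScenario",
    "GroundTruth",
    "make_gene_sets",
    "simulate_counts",
    "preset_scenario",
    "write_truth",
    "read_truth",
]

#: The discriminative panel: the 12 printed key genes plus a placeholder
#: for the unnamed 13th.
DEFAULT_PANEL = (
    "IL6", "TAGLN", "LRRC17", "CRIM1", "SERPINE2", "FOS", "ARL4C",
    "LUM", "THBS2", "EFEMP1", "BCYRN1", "FBLN5", "KEYGENE13",
)


@dataclass
class SyntheticScenario:
    """Full parameterization of one synthetic dataset.

    Parameters of note
    ------------------
    program_fold : float >= 1
        Mean fold-change of a program's genes in its member cells.
    panel_effect : float
        Log-fold activation of panel genes in +1 cells; the activated
        negative-binomial mean is ``(base + panel_pseudocount) * exp(panel_effect)``,
        so a silent gene (base 0) can be switched on via the pseudocount.
    panel_mode : {"shared", "exclusive"}
        Shared: every panel gene is shifted in every +1 cell.
        Exclusive: each +1 cell activates exactly one panel gene
        (round-robin), so the full panel is needed to recognize the
        whole embolic class.
    nb_dispersion : float > 0
        Negative-binomial dispersion theta with ``var = mu + mu^2/theta``.
    """

    n_cells: int = 3000
    n_genes: int = 2000
    n_programs: int = 6
    program_fracs: tuple = (0.30, 0.18, 0.15, 0.14, 0.12, 0.11)
    program_fold: float = 6.0
    embolic_program_index: int = 0
    panel_genes: tuple = DEFAULT_PANEL
    panel_effect: float = 1.5
    panel_mode: str = "shared"
    panel_base_mean: float | None = None
    panel_pseudocount: float = 0.0
    panel_dispersion: float | None = None
    set_size: int = 80
    set_overlap: float = 0.0
    nb_mean_shape: float = 0.4
    nb_mean_scale: float = 1.0
    nb_dispersion: float = 2.0
    libsize_logmean: float = 0.0
    libsize_logsd: float = 0.1
    cell_size_range: tuple = (0.4, 1.6)
    mito_gene_frac: float = 0.04
    mito_mean_factor: float = 6.0
    mito_dispersion: float = 50.0
    mito_cell_range: tuple = (0.5, 1.5)
    mito_outlier_boost: float = 10.0
    n_qc_outliers: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = np.asarray(self.program_fracs, dtype=float)
        if len(fracs) != self.n_programs:
            raise ValueError("program_fracs length must equal n_programs")
        if abs(fracs.sum() - 1.0) > 1e-9:
            raise ValueError("program_fracs must sum to 1 within 1e-9")
        if np.any((fracs < 0) | (fracs > 1)):
            raise ValueError("program fractions must lie in [0, 1]")
        if self.program_fold < 1:
            raise ValueError("program_fold must be >= 1")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        for name in ("nb_mean_shape", "nb_mean_scale", "libsize_logsd",
                     "mito_gene_frac", "panel_pseudocount", "set_overlap"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.panel_mode not in ("shared", "exclusive"):
            raise ValueError("panel_mode must be 'shared' or 'exclusive'")
        if not 0 <= self.embolic_program_index < self.n_programs:
            raise ValueError("embolic_program_index out of range")
        if self.n_qc_outliers < 0 or self.n_qc_outliers > self.n_cells:
            raise ValueError("n_qc_outliers out of range")

    def replace(self, **kwargs) -> "SyntheticScenario":
        return dataclasses.replace(self, **kwargs)


@dataclass
class GroundTruth:
    """Planted truth for one simulated dataset."""

    program_of_cell: np.ndarray
    embolic_label: np.ndarray       # +1 pro-embolic, -1 non-embolic
    outlier_flag: np.ndarray
    activated_panel_gene: np.ndarray = field(default=None)  # exclusive mode

    def __post_init__(self) -> None:
        self.program_of_cell = np.asarray(self.program_of_cell, dtype=int)
        self.embolic_label = np.asarray(self.embolic_label, dtype=int)
        self.outlier_flag = np.asarray(self.outlier_flag, dtype=bool)
        bad = set(np.unique(self.embolic_label)) - {-1, 1}
        if bad:
            raise ValueError(f"embolic labels must be +1/-1, found {sorted(bad)}")


def _gene_layout(scenario: SyntheticScenario):
    """Deterministic gene universe: panel genes, mito genes, background."""
    n = scenario.n_genes
    panel = list(scenario.panel_genes)
    n_mito = int(round(scenario.mito_gene_frac * n))
    if len(panel) + n_mito >= n:
        raise ValueError("gene universe too small for panel + mito genes")
    names = list(panel)
    names += [f"MT-SYN{i + 1}" for i in range(n_mito)]
    names += [f"GENE{i + 1:05d}" for i in range(n - len(names))]
    panel_idx = np.arange(len(panel))
    mito_idx = np.arange(len(panel), len(panel) + n_mito)
    background_idx = np.arange(len(panel) + n_mito, n)
    return np.array(names, dtype=object), panel_idx, mito_idx, background_idx


def make_gene_sets(scenario: SyntheticScenario) -> GeneSetCollection:
    """One gene set per program, drawn from the background gene pool.

    ``set_overlap`` is the fraction of each set shared by all sets (a
    common block), so pairwise intersections have exactly
    ``round(set_overlap * set_size)`` genes.  The embolic program's set
    is split round-robin across the four fibrin-clot pathway names;
    other programs each get one synthetic pathway set.  Panel genes are
    excluded from program sets.
    """
    if scenario.n_programs < 1:
        raise ValueError("need at least one program")
    names, _, _, bg = _gene_layout(scenario)
    size = scenario.set_size
    n_shared = int(round(scenario.set_overlap * size))
    n_own = size - n_shared
    needed = n_shared + scenario.n_programs * n_own
    if needed > len(bg):
        raise ValueError(
            f"{scenario.n_programs} sets of {size} genes (overlap {n_shared}) "
            f"need {needed} background genes, only {len(bg)} available"
        )
    shared = list(names[bg[:n_shared]])
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    cursor = n_shared
    for p in range(scenario.n_programs):
        own = list(names[bg[cursor:cursor + n_own]])
        cursor += n_own
        genes = shared + own
        if p == scenario.embolic_program_index:
            for k, pw in enumerate(EMBOLIC_PATHWAYS):
                sets[pw] = genes[k::len(EMBOLIC_PATHWAYS)]
                descriptions[pw] = f"embolic program {p} (synthetic)"
        else:
            nm = f"synthetic pathway {p}"
            sets[nm] = genes
            descriptions[nm] = f"program {p} gene set (synthetic)"
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def _program_sizes(fracs: np.ndarray, n: int) -> np.ndarray:
    """Largest-remainder quota: exact integer sizes summing to n."""
    raw = fracs * n
    sizes = np.floor(raw).astype(int)
    rem = raw - sizes
    short = n - sizes.sum()
    order = np.argsort(-rem, kind="stable")
    sizes[order[:short]] += 1
    return sizes


def program_gene_indices(scenario: SyntheticScenario) -> list[np.ndarray]:
    """Column indices of each program's gene set."""
    names, _, _, _ = _gene_layout(scenario)
    name_to_idx = {g: i for i, g in enumerate(names)}
    sets = make_gene_sets(scenario)
    per_program: list[list[str]] = [[] for _ in range(scenario.n_programs)]
    other = [p for p in range(scenario.n_programs)
             if p != scenario.embolic_program_index]
    emb_genes: list[str] = []
    for pw in EMBOLIC_PATHWAYS:
        if pw in sets.sets:
            emb_genes.extend(sets.sets[pw])
    per_program[scenario.embolic_program_index] = emb_genes
    for p in other:
        per_program[p] = sets.sets[f"synthetic pathway {p}"]
    return [np.array(sorted(name_to_idx[g] for g in set(gs)), dtype=int)
            for gs in per_program]


def simulate_counts(scenario: SyntheticScenario) -> tuple[CountMatrix, GroundTruth]:
    """Draw a UMI count matrix and its ground truth from a scenario."""
    rng = np.random.default_rng(scenario.seed)
    names, panel_idx, mito_idx, _ = _gene_layout(scenario)
    n, g = scenario.n_cells, scenario.n_genes

    base = rng.gamma(scenario.nb_mean_shape, scenario.nb_mean_scale, size=g)
    base[mito_idx] *= scenario.mito_mean_factor
    if scenario.panel_base_mean is not None:
        base[panel_idx] = scenario.panel_base_mean

    sizes = _program_sizes(np.asarray(scenario.program_fracs), n)
    program = np.repeat(np.arange(scenario.n_programs), sizes)
    program = program[rng.permutation(n)]
    label = np.where(program == scenario.embolic_program_index, 1, -1)

    outlier = np.zeros(n, dtype=bool)
    if scenario.n_qc_outliers:
        outlier[-scenario.n_qc_outliers:] = True

    size_lo, size_hi = scenario.cell_size_range
    libsize = rng.uniform(size_lo, size_hi, n) * rng.lognormal(
        scenario.libsize_logmean, scenario.libsize_logsd, n
    )
    out_pos = np.flatnonzero(outlier)
    libsize[out_pos] *= np.where(np.arange(len(out_pos)) % 2 == 0, 10.0, 0.05)

    lo, hi = scenario.mito_cell_range
    mito_factor = rng.uniform(lo, hi, size=n)
    mito_factor[outlier] *= scenario.mito_outlier_boost

    mean = np.outer(libsize, base)
    prog_genes = program_gene_indices(scenario)
    for p, idx in enumerate(prog_genes):
        members = program == p
        if members.any() and len(idx):
            mean[np.ix_(members, idx)] *= scenario.program_fold

    activated = np.full(n, -1, dtype=int)
    pos_cells = np.flatnonzero(label == 1)
    boost = np.exp(scenario.panel_effect)
    if scenario.panel_mode == "shared":
        mean[np.ix_(pos_cells, panel_idx)] = (
            (mean[np.ix_(pos_cells, panel_idx)]
             + scenario.panel_pseudocount * libsize[pos_cells, None]) * boost
        )
    else:  # exclusive: one activated panel gene per +1 cell, round-robin
        which = panel_idx[np.arange(len(pos_cells)) % len(panel_idx)]
        activated[pos_cells] = which
        mean[pos_cells, which] = (
            (mean[pos_cells, which] + scenario.panel_pseudocount * libsize[pos_cells])
            * boost
        )

    if len(mito_idx):
        mean[:, mito_idx] *= mito_factor[:, None]

    theta = np.full(g, scenario.nb_dispersion)
    theta[mito_idx] = scenario.mito_dispersion
    if scenario.panel_dispersion is not None:
        theta[panel_idx] = scenario.panel_dispersion
    p_nb = theta[None, :] / (theta[None, :] + mean)
    counts = rng.negative_binomial(theta[None, :], p_nb, size=(n, g))

    barcodes = np.array([f"CELL{i + 1:05d}" for i in range(n)], dtype=object)
    gene_ids = np.array([f"SYNG{i + 1:05d}" for i in range(g)], dtype=object)
    mito_mask = np.zeros(g, dtype=bool)
    mito_mask[mito_idx] = True
    cm = CountMatrix(
        values=sp.csr_matrix(counts),
        barcodes=barcodes,
        gene_ids=gene_ids,
        gene_names=names,
        mito_mask=mito_mask,
    )
    truth = GroundTruth(program, label, outlier, activated)
    return cm, truth


_PRESETS = {
    "mf_default": dict(
        n_cells=3000, n_programs=6,
        program_fracs=(0.30, 0.18, 0.15, 0.14, 0.12, 0.11),
        embolic_program_index=0, seed=101,
    ),
    "il_default": dict(
        n_cells=2600, n_programs=5,
        program_fracs=(0.08, 0.28, 0.24, 0.21, 0.19),
        embolic_program_index=0, seed=202,
    ),
    # Two-class table whose packaged panel drives the class separation:
    # panel genes are silent outside the pro-embolic state and each +1
    # cell switches on a single panel gene.
    "panel_default": dict(
        n_cells=2000, n_genes=120, n_programs=2, program_fracs=(0.5, 0.5),
        program_fold=1.0, embolic_program_index=0,
        panel_mode="exclusive", panel_base_mean=0.0, panel_pseudocount=0.015,
        panel_effect=7.5, panel_dispersion=20.0, cell_size_range=(0.8, 1.2),
        set_size=20, mito_gene_frac=0.0, n_qc_outliers=0, seed=303,
    ),
}


def preset_scenario(name: str) -> SyntheticScenario:
    """Packaged scenarios: ``mf_default`` (6 programs, majority-fraction
    embolic program), ``il_default`` (5 programs, small embolic
    fraction), ``panel_default`` (two-class panel-driven table)."""
    if name not in _PRESETS:
        raise ValueError(
            f"unknown preset {name!r}; available: {sorted(_PRESETS)}"
        )
    return SyntheticScenario(**_PRESETS[name])


def write_truth(truth: GroundTruth, barcodes, path) -> None:
    """Ground truth as TSV: barcode, program, label, outlier."""
    pd.DataFrame(
        {
            "barcode": np.asarray(barcodes),
            "program": truth.program_of_cell,
            "label": truth.embolic_label,
            "outlier": truth.outlier_flag.astype(int),
        }
    ).to_csv(path, sep="\t", index=False)


def read_truth(path) -> tuple[GroundTruth, np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    truth = GroundTruth(
        program_of_cell=df["program"].to_numpy(),
        embolic_label=df["label"].to_numpy(),
        outlier_flag=df["outlier"].to_numpy().astype(bool),
    )
    return truth, df["barcode"].to_numpy(dtype=object)
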