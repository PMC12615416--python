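"""Synthetic data generators with known ground truth.

Three generators cover the three data modalities of the pipeline:

* :func:`simulate_bulk` — 2-condition bulk RNA-seq count tables (4 replicates
  per condition by default) with negative-binomial noise and planted log2
  fold changes;
* :func:`simulate_sc` — a sparse cell x gene matrix with two or more
  populations (e.g. differentiated vs. modulated smooth muscle cells) carrying
  distinct marker genes, a mitochondrial gene block, and optional cells
  planted outside each single-cell QC bound;
* :func:`simulate_field` — three-channel microscopy fields (nuclear stain,
  transduction reporter, EdU) with known transduction / proliferation
  fractions, plus a confluent-monolayer wound series with a shrinking
  circular cell-free area.

Every generator is deterministic given its spec's seed and returns the truth
needed to validate the downstream stage that consumes its output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Dict, List, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

from .bulk import CONTROL, TREATED, CountMatrix
from .sc import CellMatrix
from .imaging import ChannelField

# ---------------------------------------------------------------------------
# bulk


@dataclass
class BulkSimSpec:
    """Two-condition NB count simulation with planted effects.

    ``dispersion`` is the NB alpha in the variance = mu + alpha*mu^2
    convention, shared by all genes. ``planted_effects`` maps gene id to a
    true log2 fold change (treated over control); unlisted genes are null.
    """

    n_genes: int = 2000
    n_reps_per_group: int = 4
    baseline_mean: float = 100.0
    dispersion: float = 0.05
    planted_effects: Mapping[str, float] = dc_field(default_factory=dict)
    gene_lengths: Sequence[int] | None = None
    gene_names: Sequence[str] | None = None
    seed: int = 0

    def gene_ids(self) -> List[str]:
        if self.gene_names is not None:
            return list(self.gene_names)
        return [f"g{i:05d}" for i in range(self.n_genes)]

    def validate(self) -> None:
        if self.n_genes <= 0 or self.n_reps_per_group <= 0:
            raise ValueError("n_genes and n_reps_per_group must be positive")
        if self.gene_names is not None and len(self.gene_names) != self.n_genes:
            raise ValueError("gene_names must have one entry per gene")
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be positive")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        ids = set(self.gene_ids())
        extra = set(self.planted_effects) - ids
        if extra:
            raise ValueError(f"planted_effects keys not among gene ids: {sorted(extra)[:5]}")
        if self.gene_lengths is not None and len(self.gene_lengths) != self.n_genes:
            raise ValueError("gene_lengths must have one entry per gene")


def _rnb(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """NB draws with variance mu + alpha*mu^2 (gamma-Poisson mixture)."""
    shape = 1.0 / alpha
    lam = rng.gamma(shape, mean * alpha)
    return rng.poisson(lam)


def simulate_bulk(spec: BulkSimSpec) -> tuple[CountMatrix, pd.DataFrame]:
    """Simulate a bulk count matrix; returns (CountMatrix, truth table).

    Control-group gene means equal ``baseline_mean``; for a planted gene the
    treated mean is ``baseline_mean * 2**log2fc``. The truth table records the
    true log2 fold change (0 for null genes).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    genes = spec.gene_ids()
    n = spec.n_reps_per_group

    effect = np.zeros(spec.n_genes)
    for g, lfc in spec.planted_effects.items():
        effect[genes.index(g)] = lfc

    mu_ctrl = np.full(spec.n_genes, spec.baseline_mean)
    mu_trt = mu_ctrl * 2.0**effect
    if (mu_trt <= 0).any():
        raise ValueError("non-positive treated mean after effect application")

    counts_ctrl = _rnb(rng, np.repeat(mu_ctrl[:, None], n, axis=1), spec.dispersion)
    counts_trt = _rnb(rng, np.repeat(mu_trt[:, None], n, axis=1), spec.dispersion)
    sample_ids = [f"{CONTROL}_{i+1}" for i in range(n)] + [
        f"{TREATED}_{i+1}" for i in range(n)
    ]
    counts = pd.DataFrame(
        np.hstack([counts_ctrl, counts_trt]), index=genes, columns=sample_ids
    )

    if spec.gene_lengths is None:
        lengths = rng.integers(500, 5001, size=spec.n_genes)
    else:
        lengths = np.asarray(spec.gene_lengths, dtype=int)
    condition = pd.Series(
        [CONTROL] * n + [TREATED] * n, index=sample_ids, name="condition"
    )
    cm = CountMatrix(
        counts=counts,
        gene_lengths=pd.Series(lengths, index=genes, name="length"),
        condition=condition,
    )
    truth = pd.DataFrame(
        {"true_log2fc": effect, "baseline_mean": mu_ctrl}, index=genes
    )
    return cm, truth


# ---------------------------------------------------------------------------
# single cell


@dataclass
class PopulationSpec:
    """One cell population with markers elevated by ``marker_log2_shift``."""

    name: str
    marker_genes: List[str]
    marker_log2_shift: float = 2.0


@dataclass
class ScSimSpec:
    """Multi-population single-cell NB count simulation with QC outliers.

    Per-cell depth is lognormal (``depth_log_mean``, ``depth_log_sigma``);
    the per-cell mitochondrial fraction of expression is Beta-distributed
    around ``mito_mean``; ``qc_outlier_fractions`` plants cells outside one
    named QC bound each: ``low_features``, ``high_features``, ``high_counts``,
    ``high_mito``.
    """

    n_cells_per_pop: int = 300
    populations: List[PopulationSpec] = dc_field(
        default_factory=lambda: [
            PopulationSpec("differentiated", ["CNN1", "ACTA2", "TAGLN", "MYH11"]),
            PopulationSpec("modulated", ["DCN", "LUM", "IBSP", "TMEM119", "VCAM1", "MXRA5", "PDPN"]),
        ]
    )
    n_genes: int = 6000
    n_mito_genes: int = 13
    depth_log_mean: float = math.log(3000.0)
    depth_log_sigma: float = 0.25
    mito_mean: float = 0.05
    mito_concentration: float = 100.0
    dispersion: float = 0.1
    qc_outlier_fractions: Mapping[str, float] = dc_field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells_per_pop <= 0:
            raise ValueError("n_cells_per_pop must be positive")
        if not self.populations:
            raise ValueError("at least one population required")
        markers: List[str] = []
        for p in self.populations:
            markers.extend(p.marker_genes)
        if len(markers) != len(set(markers)):
            raise ValueError("population marker sets must be disjoint")
        fr = dict(self.qc_outlier_fractions)
        bad = set(fr) - {"low_features", "high_features", "high_counts", "high_mito"}
        if bad:
            raise ValueError(f"unknown outlier classes: {sorted(bad)}")
        if any(not 0 <= v <= 1 for v in fr.values()):
            raise ValueError("outlier fractions must be in [0,1]")
        if sum(fr.values()) >= 1:
            raise ValueError("outlier fractions must sum to < 1")
        if fr.get("high_features", 0) > 0 and self.n_genes < 5000:
            raise ValueError(
                "high_features outliers need n_genes >= 5000 so the 4000-feature "
                "bound can be exceeded"
            )
        if fr.get("high_counts", 0) > 0 and self.n_genes < 4000:
            raise ValueError("high_counts outliers need n_genes >= 4000")


def _gene_symbols(spec: ScSimSpec) -> tuple[List[str], np.ndarray]:
    markers = [g for p in spec.populations for g in p.marker_genes]
    mito = [f"MT-G{i+1}" for i in range(spec.n_mito_genes)]
    n_filler = spec.n_genes - len(markers) - len(mito)
    if n_filler <= 0:
        raise ValueError("n_genes too small for markers + mito block")
    filler = [f"GENE{i:05d}" for i in range(n_filler)]
    symbols = markers + mito + filler
    mito_mask = np.zeros(spec.n_genes, dtype=bool)
    mito_mask[len(markers) : len(markers) + len(mito)] = True
    return symbols, mito_mask


def simulate_sc(spec: ScSimSpec) -> tuple[CellMatrix, pd.DataFrame]:
    """Simulate a sparse cell x gene matrix; returns (CellMatrix, truth).

    Truth columns: ``population`` and ``outlier_class`` (``"none"`` for cells
    built to pass every QC bound). Planted outliers each violate exactly their
    designated bound: <500 detected genes, >4000 detected genes, >15000 total
    counts, or >20% mitochondrial counts.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    symbols, mito_mask = _gene_symbols(spec)
    sym_index = {g: i for i, g in enumerate(symbols)}
    n_pops = len(spec.populations)
    n_cells = spec.n_cells_per_pop * n_pops

    # relative expression profile per population: lognormal baseline weights,
    # markers shifted up in their own population, mito block handled per cell
    base_w = rng.lognormal(mean=0.0, sigma=1.0, size=spec.n_genes)
    base_w[mito_mask] = 0.0
    # markers are well-expressed genes in real tissue; pin their baseline to a
    # high quantile so the planted shift is detectable at realistic depth
    marker_idx = [sym_index[g] for p in spec.populations for g in p.marker_genes]
    base_w[marker_idx] = np.quantile(base_w, 0.95)
    pop_w = {}
    for p in spec.populations:
        w = base_w.copy()
        for g in p.marker_genes:
            w[sym_index[g]] *= 2.0**p.marker_log2_shift
        pop_w[p.name] = w / w.sum()

    # assign outlier classes to disjoint cell sets
    classes = np.array(["none"] * n_cells, dtype=object)
    order = rng.permutation(n_cells)
    cursor = 0
    for cls in ("low_features", "high_features", "high_counts", "high_mito"):
        k = int(round(spec.qc_outlier_fractions.get(cls, 0.0) * n_cells))
        classes[order[cursor : cursor + k]] = cls
        cursor += k

    pops = np.repeat([p.name for p in spec.populations], spec.n_cells_per_pop)
    mito_w = np.where(mito_mask, 1.0 / spec.n_mito_genes, 0.0)
    a = spec.mito_mean * spec.mito_concentration
    b = (1 - spec.mito_mean) * spec.mito_concentration

    rows, cols, vals = [], [], []

    def draw_cell(weights: np.ndarray, depth: float, mito_share: float) -> np.ndarray:
        w = weights * (1.0 - mito_share) + mito_w * mito_share
        mu = depth * w
        lam = rng.gamma(1.0 / spec.dispersion, mu * spec.dispersion)
        return rng.poisson(lam)

    for i in range(n_cells):
        w = pop_w[pops[i]]
        cls = classes[i]
        depth = float(rng.lognormal(spec.depth_log_mean, spec.depth_log_sigma))
        mito_share = float(np.clip(rng.beta(a, b), 0.0, 0.12))
        if cls == "none":
            c = draw_cell(w, depth, mito_share)
            # guarantee the cell passes every bound (rare fix-ups, seeded)
            for _ in range(20):
                feats, tot = int((c > 0).sum()), int(c.sum())
                mito_pct = 100.0 * c[mito_mask].sum() / max(tot, 1)
                if 500 <= feats <= 4000 and tot <= 15000 and mito_pct <= 20 and tot > 0:
                    break
                depth = min(max(depth * (1.5 if feats < 500 else 0.7), 800.0), 9000.0)
                c = draw_cell(w, depth, mito_share)
        elif cls == "low_features":
            keep = rng.choice(np.flatnonzero(~mito_mask), size=300, replace=False)
            wk = np.zeros_like(w)
            wk[keep] = w[keep]
            wk /= wk.sum()
            c = draw_cell(wk, min(depth, 2000.0), mito_share)
            if (c > 0).sum() >= 500:  # cannot happen with 300 allowed genes
                raise AssertionError("low_features construction violated")
        elif cls == "high_features":
            c = draw_cell(w, depth, mito_share)
            zero = np.flatnonzero(c == 0)
            need = 4300 - int((c > 0).sum())
            if need > 0:
                c[rng.choice(zero, size=need, replace=False)] += 1
            if c.sum() > 15000 or (c > 0).sum() <= 4000:
                raise AssertionError("high_features construction violated")
        elif cls == "high_counts":
            subset = rng.choice(
                np.flatnonzero(~mito_mask), size=3200, replace=False
            )
            wk = np.zeros_like(w)
            wk[subset] = w[subset]
            wk /= wk.sum()
            c = draw_cell(wk, float(rng.uniform(18000, 22000)), mito_share)
            if c.sum() <= 15000 or (c > 0).sum() > 4000 or (c > 0).sum() < 500:
                raise AssertionError("high_counts construction violated")
        else:  # high_mito
            c = draw_cell(w, depth, float(rng.uniform(0.25, 0.35)))
            tot = c.sum()
            if 100.0 * c[mito_mask].sum() / max(tot, 1) <= 20:
                raise AssertionError("high_mito construction violated")
        nz = np.flatnonzero(c)
        rows.extend([i] * len(nz))
        cols.extend(nz.tolist())
        vals.extend(c[nz].tolist())

    counts = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(n_cells, spec.n_genes), dtype=np.int64
    )
    cell_ids = [f"cell{i:05d}" for i in range(n_cells)]
    labels = pd.Series(pops, index=cell_ids, name="population")
    cm = CellMatrix(
        counts=counts,
        cell_ids=cell_ids,
        gene_symbols=symbols,
        mito_mask=mito_mask,
        labels=labels,
    )
    truth = pd.DataFrame(
        {"population": pops, "outlier_class": classes}, index=cell_ids
    )
    return cm, truth


# ---------------------------------------------------------------------------
# imaging


@dataclass
class ImageSimSpec:
    """Three-channel nuclei field plus a shrinking circular wound series.

    ``transduced_fraction`` of nuclei carry reporter signal (count is the
    ceiling of fraction*n); EdU positivity is drawn per the two proliferating
    fractions within the transduced / untransduced subsets (rounded counts).
    ``wound_radius_series`` gives the cell-free disk radius (px) per
    timepoint, strictly decreasing.
    """

    field_shape: tuple[int, int] = (256, 256)
    n_nuclei: int = 200
    nucleus_radius_px: float = 4.0
    transduced_fraction: float = 0.9
    proliferating_fraction_transduced: float = 0.3
    proliferating_fraction_untransduced: float = 0.1
    wound_radius_series: Sequence[float] = (60.0, 30.0)
    noise_sigma: float = 0.0
    background: float = 100.0
    foreground: float = 10000.0
    seed: int = 0

    def validate(self) -> None:
        for f in (
            self.transduced_fraction,
            self.proliferating_fraction_transduced,
            self.proliferating_fraction_untransduced,
        ):
            if not 0 <= f <= 1:
                raise ValueError("fractions must lie in [0,1]")
        if self.n_nuclei <= 0 or self.nucleus_radius_px <= 0:
            raise ValueError("n_nuclei and nucleus_radius_px must be positive")
        radii = list(self.wound_radius_series)
        if any(r <= 0 for r in radii):
            raise ValueError("wound radii must be positive")
        if any(later >= earlier for earlier, later in zip(radii, radii[1:])):
            raise ValueError("wound radii must be strictly decreasing")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")


@dataclass
class FieldSim:
    """Output bundle of :func:`simulate_field`."""

    field: ChannelField
    wound_images: Dict[float, np.ndarray]  # timepoint (h) -> confluent image
    nuclei: pd.DataFrame  # per-nucleus truth: y, x, transduced, edu
    wound_truth: pd.DataFrame  # per timepoint: radius_px, area_px


class PlacementError(RuntimeError):
    """Nuclei could not be placed without overlap within the retry budget."""


def _place_nuclei(
    rng: np.random.Generator, shape: tuple[int, int], n: int, radius: float
) -> np.ndarray:
    h, w = shape
    margin = radius + 2
    min_d2 = (2 * radius + 2) ** 2
    pts: List[tuple[float, float]] = []
    attempts = 0
    while len(pts) < n:
        if attempts >= 10 * n + 1000:
            raise PlacementError(
                f"placed {len(pts)}/{n} nuclei after {attempts} attempts"
            )
        attempts += 1
        y = rng.uniform(margin, h - margin)
        x = rng.uniform(margin, w - margin)
        if all((y - py) ** 2 + (x - px) ** 2 >= min_d2 for py, px in pts):
            pts.append((y, x))
    return np.array(pts)


def _disk_stamp(img: np.ndarray, centers: np.ndarray, radius: float, value: float) -> None:
    h, w = img.shape
    yy, xx = np.ogrid[:h, :w]
    for y, x in centers:
        img[(yy - y) ** 2 + (xx - x) ** 2 <= radius**2] = value


def simulate_field(spec: ImageSimSpec) -> FieldSim:
    """Render a synthetic imaging experiment; returns a :class:`FieldSim`.

    The nuclei field carries three registered channels (nuclear, reporter,
    edu). The wound series renders a confluent monolayer as uniform foreground
    with a centered cell-free disk per timepoint (timepoints 0, 4, 8 ... h),
    emulating stitched low-magnification migration images.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.field_shape
    centers = _place_nuclei(rng, spec.field_shape, spec.n_nuclei, spec.nucleus_radius_px)

    n_trans = math.ceil(spec.transduced_fraction * spec.n_nuclei)
    idx = rng.permutation(spec.n_nuclei)
    transduced = np.zeros(spec.n_nuclei, dtype=bool)
    transduced[idx[:n_trans]] = True

    edu = np.zeros(spec.n_nuclei, dtype=bool)
    t_idx = np.flatnonzero(transduced)
    u_idx = np.flatnonzero(~transduced)
    k_t = int(round(spec.proliferating_fraction_transduced * len(t_idx)))
    k_u = int(round(spec.proliferating_fraction_untransduced * len(u_idx)))
    if k_t:
        edu[rng.choice(t_idx, size=k_t, replace=False)] = True
    if k_u:
        edu[rng.choice(u_idx, size=k_u, replace=False)] = True

    def render(mask_centers: np.ndarray) -> np.ndarray:
        img = np.full((h, w), spec.background, dtype=float)
        _disk_stamp(img, mask_centers, spec.nucleus_radius_px, spec.foreground)
        if spec.noise_sigma > 0:
            img += rng.normal(0.0, spec.noise_sigma, size=img.shape)
        return np.clip(img, 0, 65535).astype(np.uint16)

    channels = {
        "nuclear": render(centers),
        "reporter": render(centers[transduced]),
        "edu": render(centers[edu]),
    }
    field = ChannelField(channels=channels, timepoint=0.0)

    cy, cx = h / 2.0, w / 2.0
    yy, xx = np.ogrid[:h, :w]
    wound_images: Dict[float, np.ndarray] = {}
    areas = []
    for t_i, r in enumerate(spec.wound_radius_series):
        img = np.full((h, w), spec.foreground, dtype=float)
        hole = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        img[hole] = spec.background
        if spec.noise_sigma > 0:
            img += rng.normal(0.0, spec.noise_sigma, size=img.shape)
        wound_images[float(4 * t_i)] = np.clip(img, 0, 65535).astype(np.uint16)
        areas.append(int(hole.sum()))

    nuclei = pd.DataFrame(
        {
            "y": centers[:, 0],
            "x": centers[:, 1],
            "transduced": transduced,
            "edu": edu,
        }
    )
    wound_truth = pd.DataFrame(
        {
            "timepoint_h": [4.0 * i for i in range(len(areas))],
            "radius_px": list(spec.wound_radius_series),
            "area_px": areas,
        }
    )
    return FieldSim(field=field, wound_images=wound_images, nuclei=nuclei, wound_truth=wound_truth)
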