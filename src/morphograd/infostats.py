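"""Binning, entropy, mutual information, proficiency, bootstrap.

The proficiency (uncertainty coefficient) of a predictor X for a readout Y
is ``U(Y|X) = I(X;Y) / H(Y)``: the fraction of Y's information entropy
that knowing X removes. All estimators are plug-in estimates from
empirical bin frequencies, matching how the statistic is defined for
segmented-cell tables: cells are binned by coordinate (d_source, d_edge)
and by marker level, and the discrete joint distribution over bins is used
directly. No bias correction is applied; the positive finite-sample bias
of plug-in mutual information (order (bins-1)/(2n ln 2) bits) is therefore
inherited, which matters only for near-independent variables.

Entropies are reported in bits by default; proficiency is base-invariant.

The canonical coordinate binning: d_edge (in cell widths, i.e. raw um
distance / 13 um average cell diameter) into 3 fixed bins with edges at 2
and 6; d_source into 6 percentile bins; marker levels either into 2 bins
split at 10 SD above a null (no-stimulus) Gaussian fit, or into percentile
bins (4 for ratio markers).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CELL_DIAMETER_UM",
    "d_edge_from_um",
    "BinningScheme",
    "bin_records",
    "entropy",
    "mutual_information",
    "proficiency",
    "joint_labels",
    "bootstrap_proficiency",
    "BootstrapResult",
    "paper_schemes",
]

#: average cell diameter used to convert raw um distances into cell widths
CELL_DIAMETER_UM = 13.0


def d_edge_from_um(distance_um, cell_diameter: float = CELL_DIAMETER_UM):
    """Normalize a raw edge distance in um to cell widths (/ 13 um)."""
    return np.asarray(distance_um, dtype=float) / cell_diameter


@dataclass(frozen=True)
class BinningScheme:
    """How one variable is discretized.

    methods
    -------
    ``fixed_edges``: half-open intervals ``[e_k, e_{k+1})`` over interior
    edges (outermost bins unbounded).
    ``percentile``: ``n_bins`` evenly spaced quantile edges estimated from
    the data; records equal to an edge fall in the lower bin.
    ``gaussian_null``: two bins split at ``null_mean + 10 * null_sd``.
    """

    variable: str
    method: str = "percentile"
    n_bins: int = 4
    edges: tuple[float, ...] = ()
    null_mean: float = 0.0
    null_sd: float = 1.0
    null_sd_factor: float = 10.0

    def __post_init__(self):
        if self.method not in ("fixed_edges", "percentile", "gaussian_null"):
            raise ValueError(f"unknown binning method {self.method!r}")
        if self.method == "fixed_edges" and len(self.edges) == 0:
            raise ValueError("fixed_edges binning requires interior edges")
        if self.method == "percentile" and self.n_bins < 2:
            raise ValueError("percentile binning requires n_bins >= 2")
        if self.null_sd < 0:
            raise ValueError("null_sd must be non-negative")

    @classmethod
    def from_null_sample(cls, variable: str, null_values,
                         factor: float = 10.0) -> "BinningScheme":
        """Fit the Gaussian null by plain sample moments of a null sample."""
        vals = np.asarray(null_values, dtype=float)
        return cls(variable=variable, method="gaussian_null",
                   n_bins=2, null_mean=float(vals.mean()),
                   null_sd=float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                   null_sd_factor=factor)


def paper_schemes() -> dict[str, BinningScheme]:
    """The canonical coordinate schemes: 6 percentile bins for d_source and
    the fixed d_edge bins {<2, 2-6, >6} (cell widths)."""
    return {
        "d_source": BinningScheme("d_source", method="percentile", n_bins=6),
        "d_edge": BinningScheme("d_edge", method="fixed_edges",
                                edges=(2.0, 6.0), n_bins=3),
    }


def bin_records(values, scheme: BinningScheme) -> np.ndarray:
    """Map values to integer bin labels under a scheme.

    Ties at a percentile edge go to the lower bin, so repeated discrete
    values bin deterministically.
    """
    vals = np.asarray(values, dtype=float)
    if vals.ndim != 1:
        raise ValueError("bin_records expects a 1D array of values")
    if not np.all(np.isfinite(vals)):
        raise ValueError(f"non-finite values in {scheme.variable!r}")
    if scheme.method == "fixed_edges":
        edges = np.asarray(scheme.edges, dtype=float)
        return np.searchsorted(edges, vals, side="right").astype(np.int64)
    if scheme.method == "gaussian_null":
        thr = scheme.null_mean + scheme.null_sd_factor * scheme.null_sd
        return (vals >= thr).astype(np.int64)
    # percentile
    if len(np.unique(vals)) < scheme.n_bins:
        raise ValueError(
            f"{scheme.variable!r} has fewer distinct values than bins "
            f"({len(np.unique(vals))} < {scheme.n_bins})")
    qs = np.linspace(0, 1, scheme.n_bins + 1)[1:-1]
    edges = np.quantile(vals, qs)
    # side="left": a value equal to an edge lands in the lower bin
    return np.searchsorted(edges, vals, side="left").astype(np.int64)


def _counts(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty label vector")
    _, counts = np.unique(labels, return_counts=True)
    return counts


def entropy(labels, base: float = 2.0) -> float:
    """Plug-in entropy H(Y) of a label vector (bits by default)."""
    counts = _counts(labels)
    p = counts / counts.sum()
    p = p[p > 0]  # 0 log 0 := 0
    return float(-np.sum(p * np.log(p)) / np.log(base))


def mutual_information(labels_x, labels_y, base: float = 2.0) -> float:
    """Plug-in mutual information I(X;Y) from the empirical joint."""
    x = np.asarray(labels_x)
    y = np.asarray(labels_y)
    if x.shape != y.shape:
        raise ValueError("label vectors must have equal length")
    if x.size == 0:
        raise ValueError("empty label vectors")
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    nx = xi.max() + 1
    ny = yi.max() + 1
    joint = np.bincount(xi * ny + yi, minlength=nx * ny).reshape(nx, ny)
    pxy = joint / joint.sum()
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    mask = pxy > 0
    mi = np.sum(pxy[mask] * np.log(pxy[mask] / (px @ py)[mask]))
    return float(max(mi, 0.0) / np.log(base))


def proficiency(labels_x, labels_y) -> float:
    """U(Y|X) = I(X;Y)/H(Y), the fraction of Y predictable from X."""
    hy = entropy(labels_y)
    if hy == 0.0:
        raise ValueError("H(Y) = 0: Y carries no information to predict")
    return mutual_information(labels_x, labels_y) / hy


def joint_labels(*label_vectors) -> np.ndarray:
    """Flatten a tuple of predictors into one categorical label per record
    (e.g. the 6 x 3 = 18 cells of d_source x d_edge)."""
    if not label_vectors:
        raise ValueError("at least one label vector required")
    arrs = [np.asarray(v) for v in label_vectors]
    n = arrs[0].shape[0]
    if any(a.shape[0] != n for a in arrs):
        raise ValueError("label vectors must have equal length")
    out = np.zeros(n, dtype=np.int64)
    for a in arrs:
        _, ai = np.unique(a, return_inverse=True)
        out = out * (ai.max() + 1) + ai
    return out


@dataclass
class BootstrapResult:
    """Point estimate and percentile confidence interval of a proficiency."""

    point: float
    ci_low: float
    ci_high: float
    samples: np.ndarray = field(repr=False)


def bootstrap_proficiency(table: pd.DataFrame, predictors,
                          target: str,
                          schemes: dict[str, BinningScheme],
                          n_boot: int = 10000,
                          seed: int | None = None,
                          ci: float = 95.0) -> BootstrapResult:
    """Bootstrap U(target | predictors) by resampling table rows.

    ``predictors`` is a column name or a sequence of them (a joint
    predictor bins the flattened pair). Each of ``n_boot`` resamples draws
    rows with replacement, re-bins (percentile edges are re-estimated per
    resample) and recomputes U; the interval is the percentile interval at
    level ``ci``. Deterministic given ``seed``.
    """
    if len(table) == 0:
        raise ValueError("empty cell table")
    if isinstance(predictors, str):
        predictors = [predictors]
    rng = np.random.default_rng(seed)

    def u_of(df: pd.DataFrame) -> float:
        labs = [bin_records(df[p].to_numpy(), schemes[p]) for p in predictors]
        x = joint_labels(*labs) if len(labs) > 1 else labs[0]
        y = bin_records(df[target].to_numpy(), schemes[target])
        return proficiency(x, y)

    point = u_of(table)
    n = len(table)
    samples = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        samples[b] = u_of(table.iloc[idx])
    lo, hi = np.percentile(samples, [(100 - ci) / 2, 100 - (100 - ci) / 2])
    return BootstrapResult(point=point, ci_low=float(lo), ci_high=float(hi),
                           samples=samples)
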