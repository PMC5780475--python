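"""Grey-value histogram decomposition into overlapping Gaussian classes.

The quantification core: the grey-value histogram of a PTA-stained kidney is
a superposition of (nearly) Gaussian classes — pelvis/cavities, medulla,
cortex in ascending radio-opacity, plus an air class when the field of view
is not masked to the organ. The histogram envelope is modelled as a Gaussian
mixture fitted by expectation–maximization on the binned counts; the borders
between classes are the inflection points of the fitted envelope between
adjacent component means. Voxels are then classified purely by grey value
(no spatial regularization), which turns the histogram directly into
absolute and relative compartment volumes.

Everything is deterministic: EM starts from a multi-Otsu partition of the
bins, and the default envelope is the *fitted mixture density* (analytic
second derivative), with a polynomial-smoothed numeric variant of the raw
histogram available as a flagged fallback.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, signal

from .volio import VoxelGrid

__all__ = [
    "GreyHistogram", "MixtureModel", "ClassBoundaries", "CompartmentReport",
    "compute_histogram", "fit_mixture", "envelope_inflections",
    "compartment_volumes", "class_masks",
]

_SQRT2PI = float(np.sqrt(2.0 * np.pi))


# ---------------------------------------------------------------------------
# types

@dataclass
class GreyHistogram:
    """Binned grey values of the masked voxels of one scan."""

    bin_edges: np.ndarray
    counts: np.ndarray
    voxel_volume_mm3: float
    n_voxels: int

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts)
        if len(self.bin_edges) != len(self.counts) + 1:
            raise ValueError("bin_edges must be one longer than counts")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin_edges must be strictly ascending")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if int(self.counts.sum()) != self.n_voxels:
            raise ValueError("sum of counts must equal n_voxels")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def masked_volume_mm3(self) -> float:
        return self.n_voxels * self.voxel_volume_mm3


@dataclass
class MixtureModel:
    """Gaussian mixture fitted to a histogram envelope.

    ``components`` are (weight, mean, sd) in ascending order of mean.
    """

    components: list[tuple[float, float, float]]
    log_likelihood: float
    n_iterations: int
    converged: bool

    def __post_init__(self) -> None:
        self.components = [(float(w), float(m), float(s)) for w, m, s in self.components]
        w = np.array([c[0] for c in self.components])
        means = np.array([c[1] for c in self.components])
        sds = np.array([c[2] for c in self.components])
        if np.any(w <= 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be positive and sum to 1")
        if np.any(sds <= 0):
            raise ValueError("SDs must be positive")
        if np.any(np.diff(means) <= 0):
            raise ValueError("component means must be strictly ascending")

    @property
    def k(self) -> int:
        return len(self.components)

    @property
    def weights(self) -> np.ndarray:
        return np.array([c[0] for c in self.components])

    @property
    def means(self) -> np.ndarray:
        return np.array([c[1] for c in self.components])

    @property
    def sds(self) -> np.ndarray:
        return np.array([c[2] for c in self.components])

    def pdf(self, x) -> np.ndarray:
        """Mixture density — the fitted envelope (up to the count scale)."""
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x, dtype=float)
        for w, m, s in self.components:
            out += w / (s * _SQRT2PI) * np.exp(-0.5 * ((x - m) / s) ** 2)
        return out

    def d2pdf(self, x) -> np.ndarray:
        """Analytic second derivative of the envelope."""
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x, dtype=float)
        for w, m, s in self.components:
            z = (x - m) / s
            out += w / (s ** 3 * _SQRT2PI) * (z ** 2 - 1.0) * np.exp(-0.5 * z ** 2)
        return out

    def inflection_points(self) -> np.ndarray:
        """All curvature sign changes of the envelope, ascending.

        A single Gaussian has exactly two, at mean ± SD (returned
        analytically, no numerics involved).
        """
        if self.k == 1:
            _, m, s = self.components[0]
            return np.array([m - s, m + s])
        lo = self.means[0] - 4 * self.sds[0]
        hi = self.means[-1] + 4 * self.sds[-1]
        xs = np.linspace(lo, hi, 4001)
        d2 = self.d2pdf(xs)
        roots = []
        sign_change = np.nonzero(np.diff(np.sign(d2)) != 0)[0]
        for i in sign_change:
            roots.append(optimize.brentq(self.d2pdf, xs[i], xs[i + 1]))
        return np.asarray(roots)


@dataclass
class ClassBoundaries:
    """Grey-value thresholds between adjacent classes."""

    thresholds: np.ndarray
    method: str = "fitted_envelope"  # or "smoothed_numeric"

    def __post_init__(self) -> None:
        self.thresholds = np.atleast_1d(np.asarray(self.thresholds, dtype=float))
        if np.any(np.diff(self.thresholds) <= 0):
            raise ValueError("thresholds must be strictly ascending")


@dataclass
class CompartmentReport:
    """Absolute and relative volumes of the three renal compartments."""

    v_kidney_mm3: float
    v_pelvis_mm3: float
    v_medulla_mm3: float
    v_cortex_mm3: float

    def __post_init__(self) -> None:
        if self.v_kidney_mm3 <= 0:
            raise ValueError("kidney volume must be positive")
        parts = self.v_pelvis_mm3 + self.v_medulla_mm3 + self.v_cortex_mm3
        if abs(parts - self.v_kidney_mm3) > 1e-3 * self.v_kidney_mm3 + 1e-9:
            raise ValueError(
                f"compartments sum to {parts}, not V_kidney={self.v_kidney_mm3}"
            )

    @property
    def fractions_percent(self) -> dict[str, float]:
        return {
            "pelvis": 100.0 * self.v_pelvis_mm3 / self.v_kidney_mm3,
            "medulla": 100.0 * self.v_medulla_mm3 / self.v_kidney_mm3,
            "cortex": 100.0 * self.v_cortex_mm3 / self.v_kidney_mm3,
        }

    @classmethod
    def from_fractions(cls, v_kidney_mm3: float,
                       fractions_percent: tuple[float, float, float]
                       ) -> "CompartmentReport":
        """Convert relative (%) compartment portions to absolute volumes.

        The inverse of :attr:`fractions_percent`; the three percentages must
        sum to 100 within 0.1.
        """
        f = np.asarray(fractions_percent, dtype=float)
        if abs(f.sum() - 100.0) > 0.1:
            raise ValueError(f"fractions must sum to 100%, got {f.sum()}")
        v = v_kidney_mm3 * f / f.sum()
        return cls(v_kidney_mm3, *v)

    def to_dict(self) -> dict:
        fr = self.fractions_percent
        return {
            "V_kidney_mm3": self.v_kidney_mm3,
            "V_pelvis_mm3": self.v_pelvis_mm3,
            "V_medulla_mm3": self.v_medulla_mm3,
            "V_cortex_mm3": self.v_cortex_mm3,
            "pelvis_percent": fr["pelvis"],
            "medulla_percent": fr["medulla"],
            "cortex_percent": fr["cortex"],
        }


# ---------------------------------------------------------------------------
# operations

def compute_histogram(grid: VoxelGrid, mask=None, bins: int | str = 256) -> GreyHistogram:
    """Histogram of (masked) grey values.

    ``bins`` is a count of equal-width bins over the masked range (default
    256) or ``"native"`` for unit-width bins at integer grey values.
    """
    if mask is not None:
        m = np.asarray(mask, dtype=bool)
        if m.shape != grid.values.shape:
            raise ValueError("mask geometry does not match grid")
        vals = grid.values[m]
        if vals.size == 0:
            raise ValueError("empty mask")
    else:
        vals = grid.values.ravel()
    vals = np.asarray(vals, dtype=float)

    lo, hi = float(vals.min()), float(vals.max())
    if bins == "native":
        edges = np.arange(np.floor(lo) - 0.5, np.ceil(hi) + 1.5)
    else:
        if hi == lo:  # constant volume: a single occupied bin
            edges = np.array([lo - 0.5, hi + 0.5])
        else:
            edges = np.linspace(lo, hi, int(bins) + 1)
    counts, _ = np.histogram(vals, bins=edges)
    return GreyHistogram(edges, counts, grid.voxel_volume_mm3, int(vals.size))


def _otsu_init(x, c, k, pooled_mean, pooled_sd, sd_floor):
    """Initial (means, sds, weights) from a multi-Otsu partition of the bins."""
    if k == 1:
        return (np.array([pooled_mean]), np.array([pooled_sd]), np.array([1.0]))
    from skimage.filters import threshold_multiotsu

    thr = threshold_multiotsu(classes=k, hist=(c, x))
    cls = np.digitize(x, thr)
    means = np.empty(k)
    sds = np.empty(k)
    weights = np.empty(k)
    n = c.sum()
    for i in range(k):
        sel = cls == i
        ci = c[sel]
        if ci.sum() <= 0:  # empty Otsu class: fall back to pooled start
            means[i] = pooled_mean
            sds[i] = pooled_sd
            weights[i] = 1.0 / k
            continue
        means[i] = np.average(x[sel], weights=ci)
        var = np.average((x[sel] - means[i]) ** 2, weights=ci)
        sds[i] = max(np.sqrt(var), sd_floor)
        weights[i] = ci.sum() / n
    order = np.argsort(means, kind="stable")
    return means[order], sds[order], np.maximum(weights[order], 1e-6)


def fit_mixture(hist: GreyHistogram, k: int = 3, *, max_iter: int = 500,
                tol: float = 1e-8, init_means=None) -> MixtureModel:
    """Fit ``k`` Gaussian components to binned data by EM.

    Deterministic: initialization partitions the histogram at the multi-Otsu
    thresholds for ``k`` classes and starts each component at its class's
    weighted moments (a percentile start is prone to stacking two components
    on the dominant cortex mode). Convergence at ``tol`` relative change of
    the log-likelihood; a non-converged fit is returned with an honest flag.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    x = hist.bin_centers
    c = hist.counts.astype(float)
    occupied = c > 0
    if int(occupied.sum()) <= 3 * k:
        raise ValueError(
            f"too few occupied bins ({int(occupied.sum())}) to fit {k} components"
        )
    x, c = x[occupied], c[occupied]
    n = c.sum()

    pooled_mean = np.average(x, weights=c)
    pooled_sd = np.sqrt(np.average((x - pooled_mean) ** 2, weights=c))
    bin_w = np.min(np.diff(hist.bin_edges))
    sd_floor = max(bin_w / 2.0, 1e-6 * max(pooled_sd, 1.0))
    pooled_sd = max(pooled_sd, sd_floor)

    if init_means is None:
        means, sds, weights = _otsu_init(x, c, k, pooled_mean, pooled_sd, sd_floor)
    else:
        means = np.sort(np.asarray(init_means, dtype=float))
        if len(means) != k:
            raise ValueError("init_means must have length k")
        weights = np.full(k, 1.0 / k)
        sds = np.full(k, pooled_sd)

    def comp_pdf(means, sds):
        z = (x[None, :] - means[:, None]) / sds[:, None]
        return np.exp(-0.5 * z ** 2) / (sds[:, None] * _SQRT2PI)

    ll_prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        p = weights[:, None] * comp_pdf(means, sds)          # (k, bins)
        tot = p.sum(axis=0)
        tot = np.maximum(tot, 1e-300)
        ll = float(np.sum(c * np.log(tot)))
        resp = p / tot                                        # responsibilities
        nk = resp @ c
        nk = np.maximum(nk, 1e-12)
        weights = nk / n
        means = (resp @ (c * x)) / nk
        var = (resp @ (c * x ** 2)) / nk - means ** 2
        sds = np.sqrt(np.maximum(var, sd_floor ** 2))
        if ll - ll_prev <= tol * (abs(ll) + 1e-12) and it > 1:
            converged = True
            ll_prev = ll
            break
        ll_prev = ll

    order = np.argsort(means, kind="stable")
    comps = [(weights[i], means[i], sds[i]) for i in order]
    if not converged:
        warnings.warn(f"EM did not converge in {max_iter} iterations")
    return MixtureModel(comps, log_likelihood=float(ll_prev),
                        n_iterations=it, converged=converged)


def envelope_inflections(hist: GreyHistogram, model: MixtureModel,
                         method: str = "fitted_envelope") -> ClassBoundaries:
    """Class borders on the histogram envelope between adjacent means.

    For each adjacent component pair: if the envelope is bimodal over the
    interval, the border is the valley bottom bracketed by the interior
    inflection-point pair; if the classes have merged into a shoulder, it is
    the curvature zero crossing nearest the inter-mean midpoint.
    ``fitted_envelope`` (default) evaluates the analytic curvature of the
    fitted mixture; ``smoothed_numeric`` applies the same selection rule to
    a Savitzky-Golay-smoothed version of the raw histogram.
    """
    if model.k < 2:
        raise ValueError("need at least 2 components to place boundaries")
    if method not in ("fitted_envelope", "smoothed_numeric"):
        raise ValueError(f"unknown method {method!r}")

    means = model.means
    thresholds = []
    if method == "fitted_envelope":
        for a, b in zip(means[:-1], means[1:]):
            thresholds.append(_threshold_between(model.d2pdf, model.pdf, a, b))
    else:
        x = hist.bin_centers
        c = hist.counts.astype(float)
        win = min(len(c) - (1 - len(c) % 2), max(7, 2 * (len(c) // 20) + 1))
        smooth = signal.savgol_filter(c, window_length=win, polyorder=3)
        d2 = signal.savgol_filter(c, window_length=win, polyorder=3, deriv=2)

        def d2_interp(v):
            return np.interp(v, x, d2)

        def pdf_interp(v):
            return np.interp(v, x, smooth)

        for a, b in zip(means[:-1], means[1:]):
            thresholds.append(_threshold_between(d2_interp, pdf_interp, a, b))

    return ClassBoundaries(np.asarray(thresholds), method=method)


def _threshold_between(d2, pdf, a: float, b: float) -> float:
    """Class border on the envelope between two adjacent component means.

    When the envelope is bimodal over (a, b) its curvature changes sign
    twice and the pair of interior inflection points brackets a valley; the
    border is the valley bottom (for a symmetric equal mixture this is
    exactly the inter-mean midpoint). When the classes have merged into a
    shoulder there is no interior minimum and the border is the curvature
    zero crossing nearest the midpoint.
    """
    mid = 0.5 * (a + b)
    xs = np.linspace(a, b, 801)
    pv = np.asarray(pdf(xs))
    # interior local minimum of the envelope (valley between the modes)
    interior = np.nonzero((pv[1:-1] <= pv[:-2]) & (pv[1:-1] <= pv[2:]))[0] + 1
    if len(interior):
        j = interior[np.argmin(pv[interior])]
        res = optimize.minimize_scalar(
            lambda v: float(np.asarray(pdf(v))),
            bracket=(xs[j - 1], xs[j], xs[j + 1])) if pv[j - 1] > pv[j] < pv[j + 1] \
            else None
        return float(res.x) if res is not None and res.success else float(xs[j])
    vals = np.asarray(d2(xs))
    idx = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    roots = []
    for i in idx:
        try:
            roots.append(optimize.brentq(lambda v: float(np.asarray(d2(v))),
                                         xs[i], xs[i + 1]))
        except ValueError:
            continue
    if roots:
        roots = np.asarray(roots)
        return float(roots[np.argmin(np.abs(roots - mid))])
    raise ValueError(
        f"no envelope minimum and no inflection point in ({a}, {b})"
    )


_CLASS_NAMES = ("pelvis", "medulla", "cortex")


def compartment_volumes(hist: GreyHistogram, boundaries: ClassBoundaries
                        ) -> CompartmentReport:
    """Partition the masked volume into pelvis/medulla/cortex by grey value.

    Bins are assigned whole to the class containing their center, so class
    volumes partition the masked volume exactly. The brightest class (from
    the upper threshold to the maximum grey value) is the cortex.
    """
    thr = boundaries.thresholds
    if len(thr) != 2:
        raise ValueError(
            f"need exactly 2 thresholds for 3 compartments, got {len(thr)}"
        )
    lo, hi = hist.bin_edges[0], hist.bin_edges[-1]
    if not (lo <= thr[0] and thr[1] <= hi):
        raise ValueError("thresholds lie outside the histogram range")
    cls = np.digitize(hist.bin_centers, thr)
    vols = [float(hist.counts[cls == i].sum()) * hist.voxel_volume_mm3
            for i in range(3)]
    for name, v in zip(_CLASS_NAMES, vols):
        if v == 0:
            warnings.warn(f"compartment {name!r} received no voxels")
    total = float(hist.counts.sum()) * hist.voxel_volume_mm3
    return CompartmentReport(total, *vols)


def class_masks(grid: VoxelGrid, mask, boundaries: ClassBoundaries
                ) -> dict[str, np.ndarray]:
    """Per-voxel class masks (pelvis/medulla/cortex) inside an organ mask."""
    m = np.asarray(mask, dtype=bool)
    if m.shape != grid.values.shape:
        raise ValueError("mask geometry does not match grid")
    cls = np.digitize(grid.values, boundaries.thresholds)
    return {name: (cls == i) & m for i, name in enumerate(_CLASS_NAMES)}
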