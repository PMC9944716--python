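"""Similarity measures between the fixed image and the rendered DRR.

The registration cost is built from a weighted combination (NMG) of two
complementary similarities:

* **NMI** — normalized mutual information, ``1 + MI(A,B)/H(A,B)``
  (identically ``(H(A)+H(B))/H(A,B)``), bounded in [1, 2].  It captures
  the statistical (grayscale) dependence of the two images through their
  joint intensity histogram and is the standard multimodal measure.
* **GD** — gradient difference, ``sum sigma_v/(sigma_v + I_dV^2) +
  sum sigma_h/(sigma_h + I_dH^2)`` where ``I_dV = dA/dm - s*dB/dm`` and
  ``I_dH = dA/dn - s*dB/dn`` are scaled differences of the horizontal and
  vertical gradient images.  It captures spatial (edge) agreement that a
  histogram cannot see.

Raw NMI lives in [1, 2] while raw GD scales with pixel count, so a
literal 0.5/0.5 weighting would be dominated by GD.  By default both
components are therefore rescaled to [0, 1] — ``I_NMI = NMI - 1`` and
``I_GD = GD_raw / (2 N)`` — before weighting:

    NMG = alpha1 * I_NMI + alpha2 * I_GD,   cost = 1 - NMG

``normalize_components=False`` retains the literal raw combination.

All entropies use log base 2 (bits).  Histogram binning is per-image
linear min-max with nearest-bin assignment, every pixel counted, so the
metric is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volume_io import Image2D

_LOG2 = np.log(2.0)


def _as_pixels(img) -> np.ndarray:
    if isinstance(img, Image2D):
        return img.pixels
    return np.asarray(img, dtype=np.float64)


@dataclass
class JointHistogram:
    """Joint intensity histogram of two equally shaped images."""

    bins: int
    counts: np.ndarray  # (bins, bins) integers, A along rows, B along cols
    joint_p: np.ndarray
    marginal_a: np.ndarray
    marginal_b: np.ndarray
    n_samples: int


@dataclass
class GradientImages:
    gh: np.ndarray  # d/dm: horizontal, along columns
    gv: np.ndarray  # d/dn: vertical, along rows


@dataclass
class DifferenceImages:
    idv: np.ndarray  # gh_a - s * gh_b
    idh: np.ndarray  # gv_a - s * gv_b


@dataclass
class MetricConfig:
    """Knobs of the NMG similarity.

    alpha1, alpha2 : weights of the NMI and GD terms; must sum to 1
    bins : joint-histogram bin count
    sigma_v, sigma_h : GD constants; "auto" ties each to the variance of
        the corresponding gradient component of image `a` (floor 1e-8),
        making GD invariant to the intensity scale of the reference
    s : gradient scale factor; "ls" fits it by least squares per
        evaluation, a number fixes it
    normalize_components : rescale NMI and GD to [0, 1] before weighting
    """

    alpha1: float = 0.5
    alpha2: float = 0.5
    bins: int = 64
    sigma_v: float | str = "auto"
    sigma_h: float | str = "auto"
    s: float | str = "ls"
    normalize_components: bool = True

    def __post_init__(self) -> None:
        if not np.isclose(self.alpha1 + self.alpha2, 1.0):
            raise ValueError(f"alpha1 + alpha2 must be 1, got {self.alpha1 + self.alpha2}")
        if not (0 <= self.alpha1 <= 1 and 0 <= self.alpha2 <= 1):
            raise ValueError("weights must lie in [0, 1]")
        if self.bins < 2:
            raise ValueError(f"bins must be >= 2, got {self.bins}")
        for name in ("sigma_v", "sigma_h"):
            v = getattr(self, name)
            if v != "auto" and not (float(v) > 0):
                raise ValueError(f"{name} must be 'auto' or > 0, got {v}")
        if self.s != "ls":
            float(self.s)


@dataclass
class MetricReport:
    """All component values of one similarity evaluation."""

    h_a: float
    h_b: float
    h_joint: float
    mi: float
    nmi: float
    gd: float
    s_used: float
    nmg: float
    cost: float

    def to_dict(self) -> dict:
        return {k: float(getattr(self, k)) for k in
                ("h_a", "h_b", "h_joint", "mi", "nmi", "gd", "s_used", "nmg", "cost")}


def _bin_indices(px: np.ndarray, bins: int) -> np.ndarray:
    lo, hi = px.min(), px.max()
    if hi > lo:
        idx = np.floor((px - lo) / (hi - lo) * bins).astype(np.int64)
        np.clip(idx, 0, bins - 1, out=idx)
    else:
        idx = np.zeros(px.shape, dtype=np.int64)
    return idx


def joint_histogram(a, b, bins: int = 64) -> JointHistogram:
    """Joint histogram with per-image linear min-max binning."""
    pa, pb = _as_pixels(a), _as_pixels(b)
    if pa.shape != pb.shape:
        raise ValueError(f"shape mismatch: {pa.shape} vs {pb.shape}")
    if bins < 2:
        raise ValueError(f"bins must be >= 2, got {bins}")
    ia = _bin_indices(pa, bins).ravel()
    ib = _bin_indices(pb, bins).ravel()
    counts = np.bincount(ia * bins + ib, minlength=bins * bins).reshape(bins, bins)
    n = pa.size
    joint_p = counts / n
    return JointHistogram(
        bins=bins,
        counts=counts,
        joint_p=joint_p,
        marginal_a=joint_p.sum(axis=1),
        marginal_b=joint_p.sum(axis=0),
        n_samples=n,
    )


def shannon_entropy(p) -> float:
    """H = -sum p log2 p in bits, with 0 log 0 := 0."""
    p = np.asarray(p, dtype=np.float64).ravel()
    if np.any(p < -1e-12):
        raise ValueError("negative probability")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"probabilities sum to {p.sum()}, not 1")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum() / _LOG2)


def joint_entropy(h: JointHistogram) -> float:
    """H(A, B) in bits."""
    return shannon_entropy(h.joint_p)


def mutual_information(h: JointHistogram) -> float:
    """MI = H(A) + H(B) - H(A, B), bits (clipped at 0 against roundoff)."""
    mi = shannon_entropy(h.marginal_a) + shannon_entropy(h.marginal_b) - joint_entropy(h)
    return float(max(mi, 0.0))


def nmi(h: JointHistogram) -> float:
    """Normalized mutual information 1 + MI/H(A,B), in [1, 2].

    If the joint entropy is ~0 (both images constant) the limit is taken:
    2 when the constants share a bin, 1 otherwise.
    """
    hj = joint_entropy(h)
    if hj <= 1e-12:
        same_bin = np.count_nonzero(h.counts) == 1 and np.trace(h.counts) == h.n_samples
        return 2.0 if same_bin else 1.0
    return 1.0 + mutual_information(h) / hj


def gradient_images(img) -> GradientImages:
    """Finite-difference gradients: central interior, one-sided borders."""
    px = _as_pixels(img)
    if px.shape[0] < 2 or px.shape[1] < 2:
        raise ValueError("image must be at least 2x2")
    gv, gh = np.gradient(px)  # axis 0 = rows (vertical), axis 1 = cols (horizontal)
    return GradientImages(gh=gh, gv=gv)


def estimate_scale_s(a, b, mode: float | str = "ls") -> float:
    """Scale factor s matching b's gradients to a's.

    "ls" minimizes sum((gh_a - s gh_b)^2 + (gv_a - s gv_b)^2), giving
    s = <g_a, g_b> / <g_b, g_b> over both components; a number is passed
    through.  Degenerate b (zero gradients) returns 1.
    """
    if mode != "ls":
        return float(mode)
    ga, gb = gradient_images(a), gradient_images(b)
    denom = float((gb.gh**2).sum() + (gb.gv**2).sum())
    if denom < 1e-12:
        return 1.0
    num = float((ga.gh * gb.gh).sum() + (ga.gv * gb.gv).sum())
    return num / denom


def gradient_difference(a, b, cfg: MetricConfig | None = None):
    """Gradient-difference similarity of `a` (reference) and `b`.

    Returns (gd, s_used, DifferenceImages); `gd` is normalized to (0, 1]
    when cfg.normalize_components is on (maximum exactly at identical
    gradients), otherwise the raw double sum.
    """
    cfg = cfg or MetricConfig()
    pa, pb = _as_pixels(a), _as_pixels(b)
    if pa.shape != pb.shape:
        raise ValueError(f"shape mismatch: {pa.shape} vs {pb.shape}")
    ga, gb = gradient_images(pa), gradient_images(pb)
    s = estimate_scale_s(pa, pb, cfg.s)
    idv = ga.gh - s * gb.gh
    idh = ga.gv - s * gb.gv
    sigma_v = max(float(ga.gh.var()), 1e-8) if cfg.sigma_v == "auto" else float(cfg.sigma_v)
    sigma_h = max(float(ga.gv.var()), 1e-8) if cfg.sigma_h == "auto" else float(cfg.sigma_h)
    raw = float((sigma_v / (sigma_v + idv**2)).sum() + (sigma_h / (sigma_h + idh**2)).sum())
    gd = raw / (2 * pa.size) if cfg.normalize_components else raw
    return gd, s, DifferenceImages(idv=idv, idh=idh)


def nmg(a, b, cfg: MetricConfig | None = None) -> MetricReport:
    """Weighted NMI + gradient-difference similarity of `a` and `b`.

    With component normalization on (default), both terms lie in [0, 1],
    NMG = alpha1*(NMI-1) + alpha2*GD_norm in (0, 1], and cost = 1 - NMG
    is what the optimizer minimizes.  Note the measure is not symmetric
    in (a, b): the gradient scale s and auto sigmas are referenced to
    image `a`.
    """
    cfg = cfg or MetricConfig()
    hist = joint_histogram(a, b, cfg.bins)
    h_a = shannon_entropy(hist.marginal_a)
    h_b = shannon_entropy(hist.marginal_b)
    h_j = joint_entropy(hist)
    mi = mutual_information(hist)
    nmi_v = nmi(hist)
    gd, s_used, _ = gradient_difference(a, b, cfg)
    if cfg.normalize_components:
        value = cfg.alpha1 * (nmi_v - 1.0) + cfg.alpha2 * gd
        cost = 1.0 - value
    else:
        value = cfg.alpha1 * nmi_v + cfg.alpha2 * gd
        cost = -value
    return MetricReport(
        h_a=h_a, h_b=h_b, h_joint=h_j, mi=mi, nmi=nmi_v,
        gd=gd, s_used=s_used, nmg=value, cost=cost,
    )
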