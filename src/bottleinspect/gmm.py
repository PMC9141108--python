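"""Adaptive per-pixel Gaussian mixture background model.

Each pixel of the ROI carries a small set of weighted scalar Gaussians over
intensity.  The model departs from the classic fixed-K, fixed-learning-rate
mixture in three ways:

* **Dynamic component count** — an unmatched-streak counter ``V`` per
  component prunes Gaussians that have not matched for ``V_max`` consecutive
  frames (never below ``K_min``), new components are appended while
  ``K < K_max`` with weight/variance seeded from the lowest-ranked component
  (weight ``w_k(1-beta)``, variance ``(1+beta) sigma_k^2``), and components
  whose means lie within ``epsilon_merge`` gray levels are merged
  (weight-conserving moment match).
* **Motion-coupled learning rate** — a per-pixel counter ``G`` in ``[0, m]``
  (initialised to ``0.5 m``) rises by 1 while the frame-difference motion
  mask covers the pixel and decays by ``1/beta_G`` otherwise; the effective
  learning rate is ``alpha_eff = (2 G / m) alpha_base``, so recently moving
  pixels adapt up to twice as fast and quiet background barely moves.
* **Fusion** — the mixture's foreground mask is combined (logical AND by
  default) with the frame-difference motion mask, then morphologically
  closed and opened, and moving targets are captured as minimum outer
  rectangles of the connected components.

A value x matches a component when ``|x - mu| <= D sigma``.  Components are
ranked by ``w / sigma`` descending; the background is the smallest prefix
whose cumulative weight exceeds ``T_b``; a pixel is foreground when it
matches no component or only one beyond that prefix.  The matched
component's mean/variance follow the exponential updates
``mu <- (1-rho) mu + rho x``, ``sigma^2 <- (1-rho) sigma^2 + rho (x-mu')^2``
with ``rho = alpha_eff * eta(x; mu, sigma^2)`` clamped to [0, 1]
(``rho_mode='paper_eta'``) or the classic ``rho = alpha_eff / w``.

The detector contains no randomness: identical inputs give identical masks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field, replace
from typing import List, Literal, Optional, Tuple

import numpy as np
from skimage import measure, morphology

from .synthetic import ConfigurationError

_SQRT_2PI = math.sqrt(2.0 * math.pi)


@dataclass
class GMMParams:
    alpha_base: float = 0.05     # base learning rate
    D: float = 2.5               # match width in standard deviations
    T_b: float = 0.7             # background cumulative-weight proportion
    K_max: int = 5
    K_min: int = 1
    V_max: float = 15.0          # prune a component after this many unmatched frames
    beta_new: float = 0.7        # new-component weight/variance factor
    beta_G: float = 8.0          # background decay divisor of the G counter
    m: float = 32.0              # upper limit of G (G initialised to m/2)
    epsilon_merge: float = 5.0   # max |mu_a - mu_b| to merge; <= 0 disables merging
    sigma2_min: float = 4.0      # variance floor
    sigma2_init: float = 100.0   # variance of a replacement component
    w0: float = 0.05             # weight of a replacement component
    rho_mode: Literal["paper_eta", "classic"] = "paper_eta"
    adapt_learning_rate: bool = True  # False: alpha_eff = alpha_base (fixed G = m/2)

    def validate(self) -> None:
        if not (0 < self.alpha_base <= 1):
            raise ConfigurationError("alpha_base must lie in (0, 1]")
        if self.D <= 0:
            raise ConfigurationError("D must be > 0")
        if not (0 < self.T_b < 1):
            raise ConfigurationError("T_b must lie in (0, 1)")
        if self.K_min < 1 or self.K_max < self.K_min:
            raise ConfigurationError("need 1 <= K_min <= K_max")
        if self.sigma2_min <= 0:
            raise ConfigurationError("sigma2_min must be > 0")


# ---------------------------------------------------------------------------
# scalar reference operations (single pixel) — also the unit-test surface


@dataclass
class GaussianComponent:
    weight: float
    mean: float
    variance: float
    unmatched_streak: int = 0  # V, reset to 0 on match


@dataclass
class PixelMixture:
    components: List[GaussianComponent] = dc_field(default_factory=list)
    G: float = 16.0

    def sort(self) -> None:
        self.components.sort(key=lambda c: c.weight / math.sqrt(c.variance), reverse=True)

    def normalize(self) -> None:
        total = sum(c.weight for c in self.components)
        if total > 0:
            for c in self.components:
                c.weight /= total


def gaussian_density(x: float, mean: float, variance: float) -> float:
    return math.exp(-((x - mean) ** 2) / (2.0 * variance)) / (_SQRT_2PI * math.sqrt(variance))


def match(component: GaussianComponent, x: float, D: float) -> bool:
    """True iff |x - mean| <= D standard deviations."""
    return abs(x - component.mean) <= D * math.sqrt(component.variance)


def update_learning_rate(G: float, in_motion: bool, params: GMMParams) -> Tuple[float, float]:
    """Advance the G counter and return (G', alpha_eff)."""
    if params.adapt_learning_rate:
        G = G + 1.0 if in_motion else G - 1.0 / params.beta_G
        G = min(max(G, 0.0), params.m)
        return G, (2.0 * G / params.m) * params.alpha_base
    return G, params.alpha_base


def update_weights(mixture: PixelMixture, matched_index: Optional[int], alpha_eff: float,
                   normalize: bool = True) -> PixelMixture:
    """w <- (1-a) w + a M for every component (M = 1 only when matched), then renormalise."""
    for i, c in enumerate(mixture.components):
        M = 1.0 if i == matched_index else 0.0
        c.weight = (1.0 - alpha_eff) * c.weight + alpha_eff * M
    if normalize:
        mixture.normalize()
    return mixture


def update_matched(component: GaussianComponent, x: float, alpha_eff: float,
                   params: GMMParams) -> GaussianComponent:
    """Exponential mean/variance update of a matched component; V resets to 0."""
    if params.rho_mode == "paper_eta":
        rho = alpha_eff * gaussian_density(x, component.mean, component.variance)
    else:
        rho = alpha_eff / component.weight if component.weight > 0 else 1.0
    rho = min(max(rho, 0.0), 1.0)
    mean_new = (1.0 - rho) * component.mean + rho * x
    var_new = max((1.0 - rho) * component.variance + rho * (x - mean_new) ** 2,
                  params.sigma2_min)
    component.mean = mean_new
    component.variance = var_new
    component.unmatched_streak = 0
    return component


def add_component(mixture: PixelMixture, x: float, params: GMMParams) -> PixelMixture:
    """Append a component seeded from the lowest-ranked one, or replace it at K_max.

    Appended component: weight ``w_k (1 - beta_new)``, mean ``x``, variance
    ``(1 + beta_new) sigma_k^2`` where k is the lowest-ranked component.
    At K_max the lowest-priority component is replaced by
    ``(w0, x, sigma2_init)``.  Weights are renormalised.
    """
    comps = mixture.components
    if len(comps) < params.K_max:
        low = comps[-1]
        comps.append(GaussianComponent(
            weight=low.weight * (1.0 - params.beta_new),
            mean=float(x),
            variance=max((1.0 + params.beta_new) * low.variance, params.sigma2_min),
            unmatched_streak=0,
        ))
    else:
        comps[-1] = GaussianComponent(params.w0, float(x), params.sigma2_init, 0)
    mixture.normalize()
    return mixture


def merge_components(a: GaussianComponent, b: GaussianComponent) -> GaussianComponent:
    """Weight-conserving moment merge of two components."""
    total = a.weight + b.weight
    if total <= 0:
        raise ValueError("cannot merge two zero-weight components")
    return GaussianComponent(
        weight=total,
        mean=(a.weight * a.mean + b.weight * b.mean) / total,
        variance=(a.weight * a.variance + b.weight * b.variance) / total,
        unmatched_streak=min(a.unmatched_streak, b.unmatched_streak),
    )


def prune_components(mixture: PixelMixture, params: GMMParams,
                     matched_index: Optional[int] = None) -> PixelMixture:
    """Increment V of unmatched components, drop those with V > V_max while K > K_min."""
    for i, c in enumerate(mixture.components):
        if i != matched_index:
            c.unmatched_streak += 1
    keep = list(mixture.components)
    for c in sorted(mixture.components, key=lambda c: c.weight / math.sqrt(c.variance)):
        if len(keep) <= params.K_min:
            break
        if c.unmatched_streak > params.V_max:
            keep.remove(c)
    mixture.components = keep
    mixture.normalize()
    return mixture


def select_background(mixture: PixelMixture, T_b: float) -> int:
    """Smallest B with cumulative weight of the first B (priority-ordered) components > T_b."""
    cum = 0.0
    for b, c in enumerate(mixture.components, start=1):
        cum += c.weight
        if cum > T_b:
            return b
    return len(mixture.components)


# ---------------------------------------------------------------------------
# vectorised field over the ROI


class AdaptiveGMMBackgroundSubtractor:
    """Per-pixel adaptive mixture background model over a frame grid.

    Vectorised implementation of the scalar per-pixel recipe above.  Usage::

        bg = AdaptiveGMMBackgroundSubtractor(params).fit(frames[:N])
        fg_mask = bg.step(frame, motion_mask)

    ``fit`` initialises one component per pixel with the temporal mean and
    population variance (floored at ``sigma2_min``) of the init frames and
    sets ``G = 0.5 m``.  ``step`` consumes one frame plus the frame-difference
    motion mask and returns the boolean foreground mask.

    Fitted attributes (trailing underscore) are arrays of shape
    ``(rows, cols, K_max)`` (weights_, means_, variances_, streaks_, active_)
    or ``(rows, cols)`` (G_).
    """

    def __init__(self, params: GMMParams | None = None):
        self.params = params or GMMParams()

    # -- sklearn-style param plumbing -------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {"params": self.params}

    def set_params(self, **kwargs) -> "AdaptiveGMMBackgroundSubtractor":
        for k, v in kwargs.items():
            setattr(self, k, v)
        return self

    # ----------------------------------------------------------------------
    def fit(self, frames: np.ndarray) -> "AdaptiveGMMBackgroundSubtractor":
        frames = np.asarray(frames, dtype=np.float64)
        if frames.ndim == 2:
            frames = frames[None]
        if frames.size == 0:
            raise ValueError("need at least one init frame")
        p = self.params
        p.validate()
        rows, cols = frames.shape[1:]
        K = p.K_max
        self.shape_ = (rows, cols)
        self.weights_ = np.zeros((rows, cols, K))
        self.means_ = np.zeros((rows, cols, K))
        self.variances_ = np.full((rows, cols, K), p.sigma2_min)
        self.streaks_ = np.zeros((rows, cols, K))
        self.active_ = np.zeros((rows, cols, K), dtype=bool)
        self.weights_[..., 0] = 1.0
        self.means_[..., 0] = frames.mean(axis=0)
        self.variances_[..., 0] = np.maximum(frames.var(axis=0), p.sigma2_min)
        self.active_[..., 0] = True
        self.G_ = np.full((rows, cols), 0.5 * p.m)
        self.t_ = frames.shape[0]
        return self

    @property
    def n_components_(self) -> np.ndarray:
        """Per-pixel active component count K."""
        return self.active_.sum(axis=-1)

    def step(self, frame: np.ndarray, motion_mask: np.ndarray | None = None) -> np.ndarray:
        """Update the model with one frame; return the foreground mask."""
        p = self.params
        x = np.asarray(frame, dtype=np.float64)
        if x.shape != self.shape_:
            raise ValueError(f"frame shape {x.shape} != model shape {self.shape_}")
        if motion_mask is None:
            motion_mask = np.zeros(self.shape_, dtype=bool)
        elif motion_mask.shape != self.shape_:
            raise ValueError("motion mask shape mismatch")

        w, mu, var, V, act = (self.weights_, self.means_, self.variances_,
                              self.streaks_, self.active_)

        # (1) learning rate from the motion mask
        if p.adapt_learning_rate:
            self.G_ = np.clip(self.G_ + np.where(motion_mask, 1.0, -1.0 / p.beta_G),
                              0.0, p.m)
            alpha = (2.0 * self.G_ / p.m) * p.alpha_base
        else:
            alpha = np.full(self.shape_, p.alpha_base)

        xk = x[..., None]
        # (2) first matching component in priority order (arrays stay sorted)
        is_match = act & (np.abs(xk - mu) <= p.D * np.sqrt(var))
        has_match = is_match.any(axis=-1)
        midx = np.argmax(is_match, axis=-1)  # first True along K

        # (3) background prefix size B from pre-update weights
        cum = np.cumsum(w * act, axis=-1)
        B = np.argmax(cum > p.T_b, axis=-1) + 1

        fg = ~has_match | (midx >= B)

        # matched component state before the weight update (rho uses it)
        mu_m = np.take_along_axis(mu, midx[..., None], axis=-1)[..., 0]
        var_m = np.take_along_axis(var, midx[..., None], axis=-1)[..., 0]
        w_pre = np.take_along_axis(w, midx[..., None], axis=-1)[..., 0]

        # (4) weight decay/boost (Eq.-4 style) for all active components
        M = np.zeros_like(w)
        np.put_along_axis(M, midx[..., None], has_match[..., None].astype(float), axis=-1)
        ak = alpha[..., None]
        w[...] = np.where(act, (1.0 - ak) * w + ak * M, 0.0)

        # (5) matched component parameter update
        if p.rho_mode == "paper_eta":
            eta = np.exp(-((x - mu_m) ** 2) / (2.0 * var_m)) / (_SQRT_2PI * np.sqrt(var_m))
            rho = np.clip(alpha * eta, 0.0, 1.0)
        else:
            rho = np.clip(np.divide(alpha, w_pre, out=np.ones_like(alpha),
                                    where=w_pre > 0), 0.0, 1.0)
        mu_new = (1.0 - rho) * mu_m + rho * x
        var_new = np.maximum((1.0 - rho) * var_m + rho * (x - mu_new) ** 2, p.sigma2_min)
        upd = has_match[..., None] & (np.arange(p.K_max) == midx[..., None])
        mu[...] = np.where(upd, mu_new[..., None], mu)
        var[...] = np.where(upd, var_new[..., None], var)

        # (6) unmatched streaks: +1 for every active component that did not match
        V[...] = np.where(act & ~upd, V + 1.0, V)
        V[...] = np.where(upd, 0.0, V)

        # (7) pixels with no match: append or replace a component
        self._add_components(x, ~has_match)

        # (8) prune V > V_max, keeping at least K_min, lowest priority first
        self._prune()

        # (9) merge near-coincident components
        if p.epsilon_merge > 0:
            self._merge()

        self._sort_and_normalize()
        self.t_ += 1
        return fg

    # -- internals ---------------------------------------------------------
    def _add_components(self, x: np.ndarray, where: np.ndarray) -> None:
        p = self.params
        if not where.any():
            return
        w, mu, var, V, act = (self.weights_, self.means_, self.variances_,
                              self.streaks_, self.active_)
        K = act.sum(axis=-1)
        kidx = np.arange(p.K_max)

        # append while K < K_max: slot K, seeded from the lowest-ranked (slot K-1)
        app = where & (K < p.K_max)
        if app.any():
            low = np.clip(K - 1, 0, p.K_max - 1)[..., None]
            w_low = np.take_along_axis(w, low, axis=-1)[..., 0]
            var_low = np.take_along_axis(var, low, axis=-1)[..., 0]
            slot = (kidx == K[..., None]) & app[..., None]
            w[...] = np.where(slot, (w_low * (1.0 - p.beta_new))[..., None], w)
            mu[...] = np.where(slot, x[..., None], mu)
            var[...] = np.where(
                slot, np.maximum((1.0 + p.beta_new) * var_low, p.sigma2_min)[..., None], var)
            V[...] = np.where(slot, 0.0, V)
            act[...] = act | slot

        # replace at K_max: lowest-priority slot (last) gets (w0, x, sigma2_init)
        rep = where & (K >= p.K_max)
        if rep.any():
            slot = (kidx == p.K_max - 1) & rep[..., None]
            w[...] = np.where(slot, p.w0, w)
            mu[...] = np.where(slot, x[..., None], mu)
            var[...] = np.where(slot, p.sigma2_init, var)
            V[...] = np.where(slot, 0.0, V)

    def _prune(self) -> None:
        p = self.params
        act, V, w = self.active_, self.streaks_, self.weights_
        cand = act & (V > p.V_max)
        if not cand.any():
            return
        K = act.sum(axis=-1)
        removable = np.maximum(K - p.K_min, 0)
        # remove the lowest-priority candidates first (highest slot index)
        rank_from_bottom = np.cumsum(cand[..., ::-1], axis=-1)[..., ::-1] - 1
        remove = cand & (rank_from_bottom < removable[..., None])
        act[remove] = False
        w[remove] = 0.0

    def _merge(self) -> None:
        p = self.params
        K = p.K_max
        pairs = [(i, j) for i in range(K) for j in range(i + 1, K)]
        for _ in range(K - 1):
            w, mu, var, V, act = (self.weights_, self.means_, self.variances_,
                                  self.streaks_, self.active_)
            best_score = np.full(self.shape_, -np.inf)
            best_pair = np.full(self.shape_, -1, dtype=np.int64)
            for pi, (i, j) in enumerate(pairs):
                ok = act[..., i] & act[..., j]
                dmu = np.abs(mu[..., i] - mu[..., j])
                ok &= dmu <= p.epsilon_merge
                if not ok.any():
                    continue
                # highest combined weight first; ties by smallest |dmu|
                score = np.where(ok, (w[..., i] + w[..., j]) - 1e-9 * dmu, -np.inf)
                better = score > best_score
                best_score = np.where(better, score, best_score)
                best_pair = np.where(better, pi, best_pair)
            if (best_pair < 0).all():
                return
            for pi, (i, j) in enumerate(pairs):
                sel = best_pair == pi
                if not sel.any():
                    continue
                tot = w[..., i] + w[..., j]
                safe = np.where(tot > 0, tot, 1.0)
                mu_c = (w[..., i] * mu[..., i] + w[..., j] * mu[..., j]) / safe
                var_c = (w[..., i] * var[..., i] + w[..., j] * var[..., j]) / safe
                V_c = np.minimum(V[..., i], V[..., j])
                w[..., i] = np.where(sel, tot, w[..., i])
                mu[..., i] = np.where(sel, mu_c, mu[..., i])
                var[..., i] = np.where(sel, np.maximum(var_c, p.sigma2_min), var[..., i])
                V[..., i] = np.where(sel, V_c, V[..., i])
                act[..., j] = np.where(sel, False, act[..., j])
                w[..., j] = np.where(sel, 0.0, w[..., j])

    def _sort_and_normalize(self) -> None:
        w, var, act = self.weights_, self.variances_, self.active_
        priority = np.where(act, w / np.sqrt(var), -np.inf)
        order = np.argsort(-priority, axis=-1, kind="stable")
        for name in ("weights_", "means_", "variances_", "streaks_", "active_"):
            arr = getattr(self, name)
            setattr(self, name, np.take_along_axis(arr, order, axis=-1))
        total = (self.weights_ * self.active_).sum(axis=-1, keepdims=True)
        self.weights_ = np.where(self.active_,
                                 self.weights_ / np.where(total > 0, total, 1.0), 0.0)

    def background_image(self) -> np.ndarray:
        """Weight-normalised mean of each pixel's background components, as uint8."""
        p = self.params
        cum = np.cumsum(self.weights_ * self.active_, axis=-1)
        B = np.argmax(cum > p.T_b, axis=-1) + 1
        in_bg = (np.arange(p.K_max) < B[..., None]) & self.active_
        wsum = (self.weights_ * in_bg).sum(axis=-1)
        img = (self.weights_ * self.means_ * in_bg).sum(axis=-1) / np.where(wsum > 0, wsum, 1.0)
        return np.clip(np.round(img), 0, 255).astype(np.uint8)

    def apply(self, frames: np.ndarray, motion_masks: np.ndarray | None = None) -> np.ndarray:
        """Step through a stack of frames; returns the stacked foreground masks."""
        out = np.zeros(frames.shape, dtype=bool)
        for t in range(frames.shape[0]):
            mm = None if motion_masks is None else motion_masks[t]
            out[t] = self.step(frames[t], mm)
        return out


# ---------------------------------------------------------------------------
# fusion and target capture


@dataclass(frozen=True)
class DetectionBox:
    frame_index: int
    row_start: int
    row_end: int
    col_start: int
    col_end: int
    area: int  # pixels of the connected component (not the rectangle)


def fuse(fg_mask: np.ndarray, motion_mask: np.ndarray, close_kernel: int = 5,
         mode: Literal["and", "or"] = "and", open_kernel: int = 1) -> np.ndarray:
    """Combine the mixture foreground with the motion mask, close + open.

    In ``and`` mode the motion mask is morphologically *closed before* the
    combination: frame differencing only fires on the leading and trailing
    bands of a uniform moving body (the hole phenomenon), and closing the
    motion mask at the scale of the per-frame displacement fills the enclosed
    interior so that the AND lets the mixture foreground supply the complete
    target pixels while still vetoing everything outside moving regions
    (ghosts, light steps, model noise).  In ``or`` mode the closing is
    applied to the combined mask instead.  A final opening with
    ``open_kernel`` (off by default: 1-2-px-wide hairs and bubble rims would
    not survive it) removes isolated noise.
    """
    if fg_mask.shape != motion_mask.shape:
        raise ValueError("mask shape mismatch")
    fg_mask = np.asarray(fg_mask, dtype=bool)
    motion_mask = np.asarray(motion_mask, dtype=bool)
    if mode == "and":
        if close_kernel > 1:
            motion_mask = morphology.closing(
                motion_mask, morphology.footprint_rectangle((close_kernel, close_kernel)))
        fused = fg_mask & motion_mask
    else:
        fused = fg_mask | motion_mask
        if close_kernel > 1:
            fused = morphology.closing(
                fused, morphology.footprint_rectangle((close_kernel, close_kernel)))
    if open_kernel > 1:
        fused = morphology.opening(
            fused, morphology.footprint_rectangle((open_kernel, open_kernel)))
    return fused


def extract_boxes(mask: np.ndarray, min_area: int = 4, frame_index: int = 0) -> List[DetectionBox]:
    """Tight axis-aligned rectangles of 8-connected components with area >= min_area."""
    labels = measure.label(np.asarray(mask, dtype=bool), connectivity=2)
    boxes: List[DetectionBox] = []
    for region in measure.regionprops(labels):
        if region.area < min_area:
            continue
        r0, c0, r1, c1 = region.bbox
        boxes.append(DetectionBox(frame_index, r0, r1, c0, c1, int(region.area)))
    return boxes
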