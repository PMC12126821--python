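"""Native background-subtraction algorithms.

Three online per-pixel background models classify each frame's pixels into
moving foreground versus static background:

``mog2``
    Adaptive mixture of Gaussians in the Stauffer–Grimson / Zivkovic family:
    each pixel carries K Gaussian components (weight, mean, variance) updated
    recursively; components are ranked by weight/sigma and the highest-ranked
    prefix holding at least a fraction ``background_ratio`` of total weight is
    declared background.

``knn``
    Nonparametric pixel-history model: a ring buffer of N stored grey values
    per pixel; a pixel is background iff at least ``k_min`` stored samples lie
    within ``distance_threshold`` of the new value. Background pixels refresh
    a random buffer slot with probability ``p_update``.

``cnt``
    Counter-based stability model: a pixel is background once its value has
    remained within ``pixel_change_threshold`` of its last stable value for at
    least ``min_stability`` consecutive frames; any larger change resets the
    counter. Note this model detects *change*: an object that stops moving is
    absorbed into the background after ``min_stability`` frames, and vacated
    pixels remain foreground for ``min_stability`` frames.

All three are deterministic given (parameters, seed). The exact per-pixel
recursions, including tie-breaks and the order of floating-point operations,
are documented in each ``apply`` method; the test suite holds independent
scalar (per-pixel loop) re-implementations that must agree bit-for-bit.

External backends (e.g. OpenCV's GMG/LSBP/GSOC) plug in through a minimal
adapter protocol: any object exposing ``apply(frame) -> binary mask``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Protocol, runtime_checkable

import numpy as np

from .errors import ConfigurationError, ShapeMismatchError

NATIVE_ALGORITHMS = ("mog2", "knn", "cnt")
EXTERNAL_ONLY = ("gmg", "lsbp", "gsoc")


@runtime_checkable
class Subtractor(Protocol):
    """Adapter protocol: anything with apply(frame) -> boolean mask."""

    def apply(self, frame: np.ndarray) -> np.ndarray: ...


def _as_gray_f64(frame: np.ndarray, shape: Optional[tuple]) -> np.ndarray:
    frame = np.asarray(frame)
    if frame.ndim != 2:
        raise ShapeMismatchError(
            f"subtractors take grayscale frames; got shape {frame.shape}"
        )
    if shape is not None and frame.shape != shape:
        raise ShapeMismatchError(
            f"frame shape {frame.shape} does not match model shape {shape}"
        )
    return frame.astype(np.float64)


@dataclass
class MOG2Params:
    """Mixture-of-Gaussians parameters.

    The defaults are the classical literature values for this family of
    models; all are configurable.
    """

    n_components: int = 5          # K
    learning_rate: float = 0.01    # a
    match_threshold: float = 2.5   # d, in standard deviations
    background_ratio: float = 0.8  # T
    sigma_init: float = 15.0
    sigma_min: float = 4.0

    def validate(self) -> None:
        if not (0 < self.learning_rate < 1):
            raise ConfigurationError("learning_rate must be in (0, 1)")
        if not (0 < self.background_ratio < 1):
            raise ConfigurationError("background_ratio must be in (0, 1)")
        if self.n_components < 1:
            raise ConfigurationError("n_components must be >= 1")
        if self.match_threshold <= 0 or self.sigma_init <= 0 or self.sigma_min <= 0:
            raise ConfigurationError("thresholds and sigmas must be positive")


class MOG2Subtractor:
    """Per-pixel Gaussian mixture with a fixed component count.

    Update recursion applied on each ``apply(frame)`` call, per pixel with
    value x (all arithmetic float64, in this order):

    1. rank components by key w/sigma descending (stable sort);
    2. the matched component is the first in rank order with
       ``|x - mu| <= d * sigma``;
    3. classify using the *pre-update* model: the background prefix is the
       smallest rank prefix whose cumulative weight >= T; the pixel is
       foreground iff unmatched, or its matched component is outside the
       prefix;
    4. if matched (component k): ``w_j <- (1-a) w_j`` for all j, then
       ``w_k <- w_k + a``; with rho = a / w_k (updated weight) and
       delta = x - mu_k (pre-update mean): ``mu_k <- mu_k + rho delta``,
       ``var_k <- var_k + rho (delta^2 - var_k)``;
       if unmatched: the lowest-weight component (first minimum) is replaced
       by (w=a, mu=x, var=sigma_init^2), other weights untouched;
    5. floor variances at sigma_min^2 and renormalise weights to sum 1
       (sequential left-to-right summation over components).

    Unused components are initialised with zero weight (so they rank last)
    and mean 0; matching one behaves as re-seeding an empty slot.
    """

    def __init__(self, params: Optional[MOG2Params] = None, seed: int = 0):
        self.params = params or MOG2Params()
        self.params.validate()
        self._w = None
        self._mu = None
        self._var = None
        self._shape = None

    def _init_state(self, x: np.ndarray) -> None:
        K = self.params.n_components
        H, W = x.shape
        self._shape = (H, W)
        self._w = np.zeros((K, H, W))
        self._mu = np.zeros((K, H, W))
        self._var = np.full((K, H, W), self.params.sigma_init ** 2)
        self._w[0] = 1.0
        self._mu[0] = x

    def apply(self, frame: np.ndarray) -> np.ndarray:
        p = self.params
        x = _as_gray_f64(frame, self._shape)
        if self._w is None:
            self._init_state(x)
            # First frame: single matched dominant component -> background.
        K = p.n_components
        a = p.learning_rate

        sigma = np.sqrt(self._var)
        key = self._w / sigma
        order = np.argsort(-key, axis=0, kind="stable")          # (K,H,W)
        w_s = np.take_along_axis(self._w, order, axis=0)
        mu_s = np.take_along_axis(self._mu, order, axis=0)
        sig_s = np.take_along_axis(sigma, order, axis=0)

        cond = np.abs(x[None] - mu_s) <= p.match_threshold * sig_s
        matched_any = cond.any(axis=0)
        jstar = np.argmax(cond, axis=0)                          # first match
        kstar = np.take_along_axis(order, jstar[None], axis=0)[0]

        cumw = np.cumsum(w_s, axis=0)
        in_prefix = (cumw - w_s) < p.background_ratio            # strict: before-prefix mass
        matched_in_prefix = np.take_along_axis(in_prefix, jstar[None], axis=0)[0]
        foreground = (~matched_any) | (matched_any & ~matched_in_prefix)

        comp_idx = np.arange(K)[:, None, None]
        is_matched_comp = (comp_idx == kstar[None]) & matched_any[None]

        # matched branch
        w_m = (1.0 - a) * self._w
        w_m = np.where(is_matched_comp, w_m + a, w_m)
        wk = np.take_along_axis(w_m, kstar[None], axis=0)[0]
        rho = a / wk
        delta = x[None] - self._mu
        mu_m = np.where(is_matched_comp, self._mu + rho[None] * delta, self._mu)
        var_m = np.where(is_matched_comp,
                         self._var + rho[None] * (delta * delta - self._var),
                         self._var)

        # unmatched branch: replace first-minimum-weight component
        kmin = np.argmin(self._w, axis=0)
        is_repl = (comp_idx == kmin[None]) & (~matched_any[None])
        w_u = np.where(is_repl, a, self._w)
        mu_u = np.where(is_repl, x[None], self._mu)
        var_u = np.where(is_repl, p.sigma_init ** 2, self._var)

        m3 = matched_any[None]
        self._w = np.where(m3, w_m, w_u)
        self._mu = np.where(m3, mu_m, mu_u)
        self._var = np.maximum(np.where(m3, var_m, var_u), p.sigma_min ** 2)

        total = self._w[0].copy()
        for k in range(1, K):
            total = total + self._w[k]
        self._w = self._w / total
        return foreground

    @property
    def weights(self) -> np.ndarray:
        return self._w


@dataclass
class KNNParams:
    """Pixel-history k-nearest-neighbour parameters (defaults configurable)."""

    n_samples: int = 20            # N
    k_min: int = 4
    distance_threshold: float = 20.0
    p_update: float = 0.05

    def validate(self) -> None:
        if not (1 <= self.k_min <= self.n_samples):
            raise ConfigurationError("need 1 <= k_min <= n_samples")
        if not (0 <= self.p_update <= 1):
            raise ConfigurationError("p_update must be in [0, 1]")
        if self.distance_threshold < 0:
            raise ConfigurationError("distance_threshold must be >= 0")


class KNNSubtractor:
    """Pixel-history model with random background-sample refresh.

    Per ``apply(frame)`` call, in this order:

    1. classify: a pixel is background iff at least ``k_min`` of its N
       stored samples lie within ``distance_threshold`` of the new value
       (absolute grey-level distance); the buffer is filled with the first
       frame on the first call, which therefore classifies as background;
    2. draw one uniform field ``u ~ U(0,1)`` of shape (H, W), then one
       integer field ``slot ~ U{0..N-1}`` of shape (H, W), from the model's
       seeded generator (both drawn every call, including the first);
    3. for background pixels with ``u < p_update``, overwrite buffer slot
       ``slot`` with the new value.
    """

    def __init__(self, params: Optional[KNNParams] = None, seed: int = 0):
        self.params = params or KNNParams()
        self.params.validate()
        self._rng = np.random.default_rng(seed)
        self._buffer = None
        self._shape = None

    def apply(self, frame: np.ndarray) -> np.ndarray:
        p = self.params
        frame = np.asarray(frame)
        if frame.ndim != 2:
            raise ShapeMismatchError(
                f"subtractors take grayscale frames; got shape {frame.shape}"
            )
        if self._shape is not None and frame.shape != self._shape:
            raise ShapeMismatchError(
                f"frame shape {frame.shape} does not match model shape {self._shape}"
            )
        x = frame.astype(np.int16)
        if self._buffer is None:
            self._shape = frame.shape
            self._buffer = np.repeat(x[None], p.n_samples, axis=0)
        close = np.abs(self._buffer - x[None]) <= p.distance_threshold
        background = close.sum(axis=0) >= p.k_min
        u = self._rng.random(frame.shape)
        slots = self._rng.integers(0, p.n_samples, size=frame.shape)
        update = background & (u < p.p_update)
        current = np.take_along_axis(self._buffer, slots[None], axis=0)[0]
        np.put_along_axis(self._buffer, slots[None],
                          np.where(update, x, current)[None], axis=0)
        return ~background


@dataclass
class CNTParams:
    """Counter-based stability parameters (defaults configurable)."""

    min_stability: int = 15        # frames
    pixel_change_threshold: float = 10.0

    def validate(self) -> None:
        if self.min_stability < 1:
            raise ConfigurationError("min_stability must be >= 1")
        if self.pixel_change_threshold < 0:
            raise ConfigurationError("pixel_change_threshold must be >= 0")


class CNTSubtractor:
    """Counter-based model: background = unchanged for min_stability frames.

    Per ``apply(frame)``: if ``|x - v| <= pixel_change_threshold`` the
    stability counter increments, else it resets to 0 and the stable value v
    becomes x; the pixel is background iff the (updated) counter is at least
    ``min_stability``. First call initialises v = x, c = 0 (all foreground
    for min_stability >= 1).
    """

    def __init__(self, params: Optional[CNTParams] = None, seed: int = 0):
        self.params = params or CNTParams()
        self.params.validate()
        self._v = None
        self._c = None
        self._shape = None

    def apply(self, frame: np.ndarray) -> np.ndarray:
        p = self.params
        frame = np.asarray(frame)
        if frame.ndim != 2:
            raise ShapeMismatchError(
                f"subtractors take grayscale frames; got shape {frame.shape}"
            )
        if self._shape is not None and frame.shape != self._shape:
            raise ShapeMismatchError(
                f"frame shape {frame.shape} does not match model shape {self._shape}"
            )
        x = frame.astype(np.int16)
        if self._v is None:
            self._shape = frame.shape
            self._v = x.copy()
            self._c = np.zeros(frame.shape, dtype=np.int64)
            return ~(self._c >= p.min_stability)
        unchanged = np.abs(x - self._v) <= p.pixel_change_threshold
        self._c = np.where(unchanged, self._c + 1, 0)
        self._v = np.where(unchanged, self._v, x)
        return ~(self._c >= p.min_stability)


_PARAM_CLASSES = {"mog2": MOG2Params, "knn": KNNParams, "cnt": CNTParams}
_SUBTRACTOR_CLASSES = {"mog2": MOG2Subtractor, "knn": KNNSubtractor,
                       "cnt": CNTSubtractor}


def _load_external(backend_id: str):
    from importlib.metadata import entry_points

    for ep in entry_points(group="penspace.subtractors"):
        if ep.name == backend_id:
            return ep.load()
    raise ConfigurationError(
        f"no external subtractor backend registered as {backend_id!r} "
        "(entry-point group 'penspace.subtractors')"
    )


def make_subtractor(name: str, params: Optional[dict] = None,
                    seed: int = 0) -> Subtractor:
    """Build a subtractor by name with defaults filled.

    Valid names: ``mog2`` (the default algorithm), ``knn``, ``cnt``, or
    ``external:<id>`` for an installed backend. ``gmg``, ``lsbp`` and
    ``gsoc`` exist only as external backends.
    """
    params = dict(params or {})
    name = name.lower()
    if name in _PARAM_CLASSES:
        try:
            pobj = _PARAM_CLASSES[name](**params)
        except TypeError as exc:
            raise ConfigurationError(f"bad parameters for {name}: {exc}") from exc
        return _SUBTRACTOR_CLASSES[name](pobj, seed=seed)
    if name.startswith("external:"):
        factory = _load_external(name.split(":", 1)[1])
        return factory(params=params, seed=seed)
    if name in EXTERNAL_ONLY:
        raise ConfigurationError(
            f"{name!r} is only available through an external backend "
            f"(use 'external:<id>'); native algorithms: "
            f"{', '.join(NATIVE_ALGORITHMS)}"
        )
    raise ConfigurationError(
        f"unknown background-subtraction algorithm {name!r}; valid names: "
        f"{', '.join(NATIVE_ALGORITHMS)} or external:<id>"
    )
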