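"""Empirical rate-equation models of outer-wall recovery and their fitting.

Two competing models describe the growth of the band-averaged optical
density (OD) and linear dichroism (LD) during outer-wall recovery.  In
both, adsorption slows as the wall fills, giving an inverse-exponential
OD:

    OD(t) = od_base + od_amp * (1 - exp(-k_ads * t)).

*Ordered* model — molecules align with the macroscopic direction the
moment they adsorb, so LD is directly proportional to the adsorbed
amount:

    LD(t) = ld_base + c_ld * od_amp * (1 - exp(-k_ads * t)),

and the reduced LD grows monotonically.

*Disordered* model — molecules first adsorb in a transient disordered
state and only order at a second rate ``k_ord`` (two-step sequential
kinetics, dO/dt = k_ord * (M - O) with M the adsorbed amount):

    O(t) = od_amp * [1 - (k_ord e^{-k_ads t} - k_ads e^{-k_ord t})
                         / (k_ord - k_ads)],
    LD(t) = ld_base + c_ld * O(t),

which delays LD relative to OD and makes the reduced LD dip before it
recovers — the signature that discriminates the two mechanisms.

:class:`RecoveryKinetics` is the model object (data + model choice);
:meth:`RecoveryKinetics.fit` performs a joint least-squares fit of the
OD and LD series and returns a :class:`KineticsResults` with estimates,
residuals and a ``summary()`` table.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .dichroism import TimePoint

__all__ = [
    "KineticsParams",
    "KineticsResults",
    "RecoveryKinetics",
    "od_model",
    "ld_ordered",
    "ld_disordered",
    "fit_model",
]

_RATE_EQUAL_RTOL = 1e-9


@dataclasses.dataclass(frozen=True)
class KineticsParams:
    """Parameters of the recovery rate models.

    ``od_base``/``ld_base`` are the inner-wall contributions present at
    t = 0; ``od_amp`` the recovered-wall amplitude; ``k_ads`` the
    adsorption rate (1/time); ``c_ld`` the LD produced per unit OD of
    ordered material (bounded by the reduced-LD maximum of 3); ``k_ord``
    the ordering rate, used by the disordered model only.
    """

    od_base: float
    od_amp: float
    k_ads: float
    ld_base: float = 0.0
    c_ld: float = 1.0
    k_ord: float | None = None

    def __post_init__(self) -> None:
        if self.k_ads <= 0:
            raise ValueError("k_ads must be > 0")
        if self.k_ord is not None and self.k_ord <= 0:
            raise ValueError("k_ord must be > 0")
        if self.od_amp < 0 or self.od_base < 0:
            raise ValueError("amplitudes and baselines must be >= 0")
        if not 0.0 <= self.c_ld <= 3.0:
            raise ValueError("c_ld must lie in [0, 3]")


def _check_t(t) -> np.ndarray:
    t = np.asarray(t, float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    return t


def od_model(t, p: KineticsParams) -> np.ndarray:
    """Inverse-exponential optical density, shared by both models."""
    t = _check_t(t)
    return p.od_base + p.od_amp * (1.0 - np.exp(-p.k_ads * t))


def ld_ordered(t, p: KineticsParams) -> np.ndarray:
    """LD proportional to the adsorbed amount (immediate ordering)."""
    t = _check_t(t)
    return p.ld_base + p.c_ld * p.od_amp * (1.0 - np.exp(-p.k_ads * t))


def ordered_population(t, p: KineticsParams) -> np.ndarray:
    """O(t) of the two-step model; handles the equal-rate limit analytically."""
    t = _check_t(t)
    if p.k_ord is None:
        raise ValueError("disordered model requires k_ord")
    ka, ko = p.k_ads, p.k_ord
    if abs(ko - ka) <= _RATE_EQUAL_RTOL * ka:
        return p.od_amp * (1.0 - (1.0 + ka * t) * np.exp(-ka * t))
    return p.od_amp * (
        1.0 - (ko * np.exp(-ka * t) - ka * np.exp(-ko * t)) / (ko - ka)
    )


def ld_disordered(t, p: KineticsParams) -> np.ndarray:
    """LD carried by the ordered population only (delayed ordering)."""
    return p.ld_base + p.c_ld * ordered_population(t, p)


@dataclasses.dataclass(frozen=True)
class KineticsResults:
    """Joint OD+LD least-squares fit of one rate model.

    ``flags`` collects degeneracy/convergence warnings (empty for a
    clean fit); ``sse`` is the joint sum of squared residuals.
    """

    params: KineticsParams
    model_tag: str
    sse: float
    residuals: np.ndarray
    t: np.ndarray
    od: np.ndarray
    ld: np.ndarray
    success: bool
    flags: tuple[str, ...] = ()
    message: str = ""

    def __post_init__(self) -> None:
        if self.sse < 0:
            raise ValueError("sse must be >= 0")

    def predict(self, t=None) -> pd.DataFrame:
        """Model OD, LD and reduced LD on a time grid (default: the data's)."""
        t = self.t if t is None else _check_t(t)
        od = od_model(t, self.params)
        ld = (ld_ordered if self.model_tag == "ordered" else ld_disordered)(
            t, self.params
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            ld_r = np.where(od > 0, ld / od, np.nan)
        return pd.DataFrame({"t": t, "od": od, "ld": ld, "ld_r": ld_r})

    def summary(self) -> str:
        p = self.params
        lines = [
            f"Recovery kinetics fit — {self.model_tag} model",
            "=" * 46,
            f"{'n observations':<22}{len(self.t)}",
            f"{'joint SSE':<22}{self.sse:.6g}",
            f"{'converged':<22}{self.success}",
            "-" * 46,
            f"{'od_base':<22}{p.od_base:.6g}",
            f"{'od_amp':<22}{p.od_amp:.6g}",
            f"{'k_ads':<22}{p.k_ads:.6g}",
            f"{'ld_base':<22}{p.ld_base:.6g}",
            f"{'c_ld':<22}{p.c_ld:.6g}",
        ]
        if p.k_ord is not None:
            lines.append(f"{'k_ord':<22}{p.k_ord:.6g}")
        if self.flags:
            lines.append("-" * 46)
            for flag in self.flags:
                lines.append(f"flag: {flag}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Data points and fitted curves for OD and LD."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        dense = np.linspace(self.t.min(), self.t.max(), 200)
        pred = self.predict(dense)
        ax.plot(self.t, self.od, "o", label="OD data")
        ax.plot(self.t, self.ld, "s", label="LD data")
        ax.plot(pred.t, pred.od, "-", label="OD fit")
        ax.plot(pred.t, pred.ld, "--", label="LD fit")
        ax.set_xlabel("time")
        ax.legend()
        return ax


class RecoveryKinetics:
    """Rate-equation model of an OD/LD recovery series.

    Parameters
    ----------
    t, od, ld : 1-D arrays of equal length (>= 5 points).
    model : ``"ordered"`` or ``"disordered"``.
    weights : (w_od, w_ld) relative weights of the two series in the
        joint objective; default equal.
    """

    def __init__(self, t, od, ld, model: str = "disordered",
                 weights: tuple[float, float] = (1.0, 1.0)):
        if model not in ("ordered", "disordered"):
            raise ValueError("model must be 'ordered' or 'disordered'")
        self.t = _check_t(t)
        self.od = np.asarray(od, float)
        self.ld = np.asarray(ld, float)
        if not len(self.t) == len(self.od) == len(self.ld):
            raise ValueError("t, od, ld must have equal length")
        if len(self.t) < 5:
            raise ValueError("need at least 5 points")
        self.model = model
        self.weights = weights

    @classmethod
    def from_timepoints(
        cls, points: Sequence[TimePoint], model: str = "disordered", **kw
    ) -> "RecoveryKinetics":
        return cls(
            [p.t for p in points],
            [p.od for p in points],
            [p.ld for p in points],
            model,
            **kw,
        )

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, model: str = "disordered", **kw
    ) -> "RecoveryKinetics":
        return cls(df["t"], df["od"], df["ld"], model, **kw)

    # parameter vector layout: ordered    -> od_base, od_amp, k_ads, ld_base, c_ld
    #                          disordered -> ... + k_ord
    @property
    def _n_params(self) -> int:
        return 5 if self.model == "ordered" else 6

    def _to_params(self, x: np.ndarray) -> KineticsParams:
        k_ord = float(x[5]) if self.model == "disordered" else None
        return KineticsParams(
            od_base=float(x[0]), od_amp=float(x[1]), k_ads=float(x[2]),
            ld_base=float(x[3]), c_ld=float(x[4]), k_ord=k_ord,
        )

    def _residuals(self, x: np.ndarray) -> np.ndarray:
        p = self._to_params(x)
        ld_fn = ld_ordered if self.model == "ordered" else ld_disordered
        w_od, w_ld = self.weights
        return np.concatenate(
            [
                w_od * (od_model(self.t, p) - self.od),
                w_ld * (ld_fn(self.t, p) - self.ld),
            ]
        )

    def _default_init(self) -> np.ndarray:
        od0, od_inf = self.od[0], self.od[-1]
        amp = max(od_inf - od0, 1e-12)
        # time at which half the rise is reached -> rate scale
        half = od0 + 0.5 * amp
        above = np.flatnonzero(self.od >= half)
        t_half = self.t[above[0]] if len(above) and self.t[above[0]] > 0 else (
            self.t[-1] / 2 if self.t[-1] > 0 else 1.0
        )
        k = np.log(2.0) / t_half
        ld_rise = max(self.ld[-1] - self.ld[0], 0.0)
        c = min(max(ld_rise / amp, 1e-6), 3.0)
        x = [max(od0, 0.0), amp, k, max(self.ld[0], 0.0), c]
        if self.model == "disordered":
            x.append(k)
        return np.asarray(x)

    def _default_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        scale = max(np.max(self.od), 1e-9)
        t_span = max(self.t[-1], 1e-9)
        lo = [0.0, 0.0, 1e-6 / t_span, 0.0, 0.0]
        hi = [10 * scale, 10 * scale, 1e4 / t_span * 100, 10 * scale, 3.0]
        if self.model == "disordered":
            lo.append(1e-6 / t_span)
            hi.append(1e6 / t_span)
        return np.asarray(lo), np.asarray(hi)

    def fit(self, init=None, bounds=None) -> KineticsResults:
        """Joint least-squares fit; deterministic given ``init``.

        A degenerate series (no OD rise, hence unidentifiable rate) is
        returned flagged rather than raising.
        """
        x0 = self._default_init() if init is None else np.asarray(init, float)
        lo, hi = self._default_bounds() if bounds is None else (
            np.asarray(bounds[0], float), np.asarray(bounds[1], float)
        )
        x0 = np.clip(x0, lo, hi)
        result = least_squares(self._residuals, x0, bounds=(lo, hi),
                               method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12)
        params = self._to_params(result.x)
        residuals = self._residuals(result.x)
        sse = float(np.sum(residuals**2))
        flags = []
        data_scale = max(np.max(self.od) - np.min(self.od), np.max(self.od), 1e-12)
        if params.od_amp < 1e-3 * data_scale:
            flags.append("od_amp ~ 0: adsorption rate unidentifiable")
        if not result.success:
            flags.append("optimizer did not report convergence")
        return KineticsResults(
            params=params,
            model_tag=self.model,
            sse=sse,
            residuals=residuals,
            t=self.t,
            od=self.od,
            ld=self.ld,
            success=result.success and not flags,
            flags=tuple(flags),
            message=result.message,
        )


def fit_model(
    points: Sequence[TimePoint], model_tag: str, init=None, bounds=None,
    weights: tuple[float, float] = (1.0, 1.0),
) -> KineticsResults:
    """Fit one rate model to a band-averaged time series."""
    model = RecoveryKinetics.from_timepoints(points, model_tag, weights=weights)
    return model.fit(init=init, bounds=bounds)
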