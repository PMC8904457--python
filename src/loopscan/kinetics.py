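"""Enzyme-kinetics and binding models with a Model/Results interface.

Each assay of a deletion-scan characterisation maps onto one model
class, constructed from a concentration-rate design and fitted with
``fit()``, which returns a :class:`KineticsResults` carrying estimates,
asymptotic standard errors, residuals and a ``summary()`` table:

* :class:`MichaelisMenten` — v = Vmax*S / (KM + S); kcat = Vmax/[E].
* :class:`CompetitiveInhibition` — v = V*S / (KM*(1+I/Ki) + S) with the
  substrate concentration and KM fixed from the substrate titration.
* :class:`HyperbolicBinding` — v = v0 + (vinf-v0)*T / (Kd + T) for an
  activity read-out of cofactor titration.
* :class:`InitialRate` — ordinary least-squares slope of a progress
  curve over its initial linear window (default: the first 5 minutes).

Fits are unweighted nonlinear least squares.  Positive-definite
parameters (KM, Ki, Kd, Vmax, V) are fitted on the log scale; reported
standard errors are delta-method back-transforms.  Starting values come
from linearisations (Hanes-Woolf for the Michaelis-Menten model).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import linregress


class FitError(RuntimeError):
    """Raised when a fit cannot be performed or is rejected."""


@dataclass
class RateSeries:
    """One assay series: concentrations (or times) vs. rates (or signal).

    ``x`` must be non-negative and strictly increasing; at least four
    points are required for fitting.  ``enzyme_conc`` (same unit family
    as the rates) converts Vmax to kcat.
    """

    x: np.ndarray
    v: np.ndarray
    enzyme_conc: float = np.nan
    assay: str = ""
    replicate: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.x.shape != self.v.shape:
            raise ValueError("x and v must have equal length")
        if self.x.size < 4:
            raise ValueError(f"need >= 4 points for fitting, got {self.x.size}")
        if (self.x < 0).any():
            raise ValueError("negative concentrations/times")
        if (np.diff(self.x) <= 0).any():
            raise ValueError("x must be strictly increasing")

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, x: str = "x", v: str = "v", **kwargs
    ) -> "RateSeries":
        return cls(x=df[x].to_numpy(), v=df[v].to_numpy(), **kwargs)


def average_replicates(series_list: list[RateSeries]) -> RateSeries:
    """Average rates across replicate series sharing one design."""
    ref = series_list[0]
    for s in series_list[1:]:
        if not np.array_equal(s.x, ref.x):
            raise ValueError("replicates have different designs")
    v = np.mean([s.v for s in series_list], axis=0)
    return RateSeries(
        x=ref.x.copy(), v=v, enzyme_conc=ref.enzyme_conc,
        assay=ref.assay, replicate=-1, metadata=dict(ref.metadata),
    )


@dataclass
class KineticsResults:
    """Fit results: point estimates, standard errors and diagnostics."""

    model_name: str
    params: dict[str, float]
    bse: dict[str, float]
    residuals: np.ndarray
    fitted: np.ndarray
    series: RateSeries
    extra: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    @property
    def rss(self) -> float:
        return float((self.residuals ** 2).sum())

    @property
    def rsquared(self) -> float:
        tss = float(((self.series.v - self.series.v.mean()) ** 2).sum())
        if tss == 0:
            return 1.0
        return 1.0 - self.rss / tss

    def summary(self) -> str:
        buf = io.StringIO()
        buf.write(f"{self.model_name} fit\n")
        buf.write(f"{'=' * 44}\n")
        buf.write(f"n points: {self.series.x.size:>6d}    ")
        buf.write(f"R^2: {self.rsquared:.4f}    RSS: {self.rss:.4g}\n")
        buf.write(f"{'-' * 44}\n")
        buf.write(f"{'parameter':<14}{'estimate':>14}{'std err':>14}\n")
        for name, val in self.params.items():
            se = self.bse.get(name, float("nan"))
            buf.write(f"{name:<14}{val:>14.6g}{se:>14.3g}\n")
        for key, val in self.extra.items():
            buf.write(f"{key:<14}{val:>14.6g}\n")
        for w in self.warnings:
            buf.write(f"warning: {w}\n")
        return buf.getvalue()


def _fit_log_params(model_fn, x, y, p0_log, maxfev=20000):
    """curve_fit in log-parameter space; returns estimates, SEs (delta method)."""
    popt, pcov = curve_fit(model_fn, x, y, p0=p0_log, maxfev=maxfev)
    est = np.exp(popt)
    var_log = np.diag(pcov)
    se = est * np.sqrt(np.clip(var_log, 0, np.inf))
    return est, se, popt


class _KineticModel:
    """Shared construction for the concentration-rate models."""

    def __init__(self, series: RateSeries):
        self.series = series

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, x: str = "x", v: str = "v", **kw):
        return cls(RateSeries.from_dataframe(df, x=x, v=v, **kw))


class MichaelisMenten(_KineticModel):
    """Michaelis-Menten substrate titration: v = Vmax*S / (KM + S)."""

    def __init__(self, series: RateSeries, min_levels: int = 5):
        super().__init__(series)
        nonzero = int((series.x > 0).sum())
        if nonzero < min_levels - 1 or series.x.size < min_levels:
            raise FitError(
                f"need >= {min_levels} substrate levels, got {series.x.size}"
            )

    @staticmethod
    def predict(s: np.ndarray, vmax: float, km: float) -> np.ndarray:
        return vmax * s / (km + s)

    def _start_values(self) -> tuple[float, float]:
        """Hanes-Woolf linearisation: S/v = S/Vmax + KM/Vmax."""
        x, v = self.series.x, self.series.v
        mask = (x > 0) & (v > 0)
        if mask.sum() >= 3:
            reg = linregress(x[mask], x[mask] / v[mask])
            if reg.slope > 0 and reg.intercept > 0:
                vmax0 = 1.0 / reg.slope
                km0 = reg.intercept * vmax0
                return vmax0, km0
        vmax0 = float(v.max()) * 1.2 if v.max() > 0 else 1.0
        km0 = float(np.median(x[x > 0])) if (x > 0).any() else 1.0
        return vmax0, km0

    def fit(self) -> KineticsResults:
        x, v = self.series.x, self.series.v
        vmax0, km0 = self._start_values()

        def f(s, log_vmax, log_km):
            return self.predict(s, np.exp(log_vmax), np.exp(log_km))

        try:
            est, se, _ = _fit_log_params(
                f, x, v, [np.log(vmax0), np.log(km0)]
            )
        except RuntimeError as exc:
            raise FitError(
                f"Michaelis-Menten fit did not converge "
                f"(start Vmax={vmax0:.4g}, KM={km0:.4g}): {exc}"
            ) from exc
        vmax, km = est
        fitted = self.predict(x, vmax, km)
        params = {"V_max": float(vmax), "K_M": float(km)}
        bse = {"V_max": float(se[0]), "K_M": float(se[1])}
        extra = {}
        e = self.series.enzyme_conc
        if np.isfinite(e) and e > 0:
            params["k_cat"] = float(vmax / e)
            bse["k_cat"] = float(se[0] / e)
            extra["kcat_over_km"] = params["k_cat"] / params["K_M"]
        return KineticsResults(
            model_name="Michaelis-Menten",
            params=params, bse=bse,
            residuals=v - fitted, fitted=fitted,
            series=self.series, extra=extra,
        )


class CompetitiveInhibition(_KineticModel):
    """Competitive inhibition at fixed substrate:
    v = V*S / (KM*(1 + I/Ki) + S), with S and KM supplied."""

    def __init__(
        self, series: RateSeries, km: float,
        s_fixed: float | None = None, min_levels: int = 5,
    ):
        super().__init__(series)
        if series.x.size < min_levels:
            raise FitError(
                f"need >= {min_levels} inhibitor levels, got {series.x.size}"
            )
        if series.x[0] != 0:
            raise FitError("inhibitor series must include I = 0")
        if km <= 0:
            raise FitError("KM must be positive")
        self.km = float(km)
        if s_fixed is None:
            s_fixed = series.metadata.get("s_fixed_mm", 1.0)
        self.s_fixed = float(s_fixed)
        v = series.v
        # reject a flat series: no inhibition signal to fit
        if v[0] <= 0 or (v.min() > 0.8 * v[0]):
            raise FitError(
                "no inhibition signal: rates do not decrease with inhibitor"
            )

    def predict(self, i: np.ndarray, v_lim: float, ki: float) -> np.ndarray:
        return v_lim * self.s_fixed / (
            self.km * (1.0 + i / ki) + self.s_fixed
        )

    def fit(self) -> KineticsResults:
        x, v = self.series.x, self.series.v
        v0 = v[0]
        v_lim0 = v0 * (self.km + self.s_fixed) / self.s_fixed
        half = v0 / 2.0
        above = x[v > half]
        ki0 = float(above.max()) if above.size else float(np.median(x[x > 0]))
        ki0 = max(ki0, 1e-6)

        def f(i, log_v, log_ki):
            return self.predict(i, np.exp(log_v), np.exp(log_ki))

        try:
            est, se, _ = _fit_log_params(
                f, x, v, [np.log(v_lim0), np.log(ki0)]
            )
        except RuntimeError as exc:
            raise FitError(
                f"competitive-inhibition fit did not converge "
                f"(start V={v_lim0:.4g}, Ki={ki0:.4g}): {exc}"
            ) from exc
        v_lim, ki = est
        fitted = self.predict(x, v_lim, ki)
        return KineticsResults(
            model_name="Competitive inhibition",
            params={"V": float(v_lim), "K_i": float(ki)},
            bse={"V": float(se[0]), "K_i": float(se[1])},
            residuals=v - fitted, fitted=fitted, series=self.series,
            extra={"S_fixed": self.s_fixed, "K_M_input": self.km},
        )


class HyperbolicBinding(_KineticModel):
    """Hyperbolic activity titration: v = v0 + (vinf - v0)*T / (Kd + T).

    A tight-binding quadratic variant is available with
    ``tight_binding=True`` and a known total enzyme concentration, for
    titrations where the titrant does not greatly exceed the enzyme.
    """

    def __init__(
        self, series: RateSeries, min_levels: int = 5,
        tight_binding: bool = False,
    ):
        super().__init__(series)
        if series.x.size < min_levels:
            raise FitError(
                f"need >= {min_levels} titrant levels, got {series.x.size}"
            )
        if series.x[0] != 0:
            raise FitError("titration must include T = 0")
        self.tight_binding = tight_binding
        if tight_binding and not (
            np.isfinite(series.enzyme_conc) and series.enzyme_conc > 0
        ):
            raise FitError("tight-binding fit requires the enzyme concentration")

    def predict(
        self, t: np.ndarray, v0: float, vinf: float, kd: float
    ) -> np.ndarray:
        if not self.tight_binding:
            return v0 + (vinf - v0) * t / (kd + t)
        e = self.series.enzyme_conc
        b = e + t + kd
        bound = (b - np.sqrt(b * b - 4.0 * e * t)) / (2.0 * e)
        return v0 + (vinf - v0) * bound

    def fit(self) -> KineticsResults:
        x, v = self.series.x, self.series.v
        v0_0 = float(v[0])
        vinf0 = float(v[-1])
        half = v0_0 + 0.5 * (vinf0 - v0_0)
        cross = x[np.abs(v - half).argmin()]
        kd0 = max(float(cross), float(x[x > 0].min()) / 2.0)

        def f(t, v0p, log_span, log_kd):
            return self.predict(
                t, v0p, v0p + np.exp(log_span), np.exp(log_kd)
            )

        span0 = max(vinf0 - v0_0, 1e-9)
        try:
            popt, pcov = curve_fit(
                f, x, v, p0=[v0_0, np.log(span0), np.log(kd0)], maxfev=20000
            )
        except RuntimeError as exc:
            raise FitError(
                f"binding fit did not converge (start v0={v0_0:.4g}, "
                f"Kd={kd0:.4g}): {exc}"
            ) from exc
        v0_est = popt[0]
        span = np.exp(popt[1])
        kd = np.exp(popt[2])
        var = np.diag(pcov)
        se_v0 = float(np.sqrt(max(var[0], 0)))
        se_span = float(span * np.sqrt(max(var[1], 0)))
        se_kd = float(kd * np.sqrt(max(var[2], 0)))
        fitted = self.predict(x, v0_est, v0_est + span, kd)
        warn = []
        if x.max() < kd:
            warn.append(
                f"saturation not approached: max titrant {x.max():.3g} "
                f"< fitted Kd {kd:.3g}"
            )
        return KineticsResults(
            model_name="Hyperbolic binding"
            + (" (tight-binding)" if self.tight_binding else ""),
            params={
                "v0": float(v0_est),
                "v_inf": float(v0_est + span),
                "K_d": float(kd),
            },
            bse={"v0": se_v0, "v_inf": se_span, "K_d": se_kd},
            residuals=v - fitted, fitted=fitted, series=self.series,
            warnings=warn,
        )


class InitialRate(_KineticModel):
    """OLS slope of a progress curve over its initial linear window."""

    def __init__(self, series: RateSeries, window_min: float = 5.0):
        super().__init__(series)
        self.window_min = float(window_min)
        if int((series.x <= self.window_min).sum()) < 3:
            raise FitError(
                f"fewer than 3 points within the first {window_min} minutes"
            )

    def fit(self) -> KineticsResults:
        mask = self.series.x <= self.window_min
        t, y = self.series.x[mask], self.series.v[mask]
        reg = linregress(t, y)
        fitted_window = reg.intercept + reg.slope * t
        return KineticsResults(
            model_name="Initial rate (linear)",
            params={"slope": float(reg.slope), "intercept": float(reg.intercept)},
            bse={"slope": float(reg.stderr), "intercept": float(reg.intercept_stderr)},
            residuals=y - fitted_window,
            fitted=fitted_window,
            series=self.series,
            extra={"window_min": self.window_min, "n_window": int(mask.sum())},
        )


def initial_rate(series: RateSeries, window_min: float = 5.0) -> float:
    """Convenience wrapper: the fitted initial-rate slope."""
    return InitialRate(series, window_min=window_min).fit().params["slope"]


# ---------------------------------------------------------------------------
# Variant summary tables

PERCENT_COLUMNS = {
    "kcat_over_km": "pct_kcat_over_km",
    "ki": "pct_ki",
    "fx_activation": "pct_fx_activation",
}


def normalize_to_reference(
    table: pd.DataFrame, reference_id: str = "WT", id_column: str = "variant"
) -> pd.DataFrame:
    """Add WT-normalised percentage columns to a per-variant metric table.

    Percentages are 100 * variant / reference for every metric named in
    ``PERCENT_COLUMNS`` that is present.  For the inhibition constant the
    convention is "percentage K_i of the reference", i.e. the same
    variant/reference ratio: values above 100% mean weaker inhibitor
    binding than the reference (the reciprocal reference/variant ratio is
    emitted alongside as ``pct_ki_inverse`` so both directions are
    available).  The reference row reads 100% in every percentage column.
    """
    if reference_id not in set(table[id_column]):
        raise ValueError(f"reference {reference_id!r} not present in table")
    out = table.copy()
    ref_row = out[out[id_column] == reference_id].iloc[0]
    for metric, pct_name in PERCENT_COLUMNS.items():
        if metric not in out.columns:
            continue
        ref_val = ref_row[metric]
        if not np.isfinite(ref_val) or ref_val == 0:
            raise ValueError(
                f"reference metric {metric!r} is zero or missing"
            )
        out[pct_name] = 100.0 * out[metric] / ref_val
        if metric == "ki":
            out["pct_ki_inverse"] = 100.0 * ref_val / out[metric]
    return out


def build_heatmap_table(
    fits: pd.DataFrame,
    reference_id: str = "WT",
    sort: bool = True,
    figure_path: str | Path | None = None,
) -> pd.DataFrame:
    """Assemble the WT-normalised variant characterisation table.

    ``fits`` carries one row per variant with columns ``variant``,
    ``loop_length``, ``del_start`` and the fitted metrics (kd, km, kcat,
    kcat_over_km, ki, fx_activation — missing metrics yield blank
    columns).  Rows are sorted by loop length (descending, wild type
    first) then deletion position.  When ``figure_path`` is given, a
    diverging-scale heatmap of the percentage columns (blue above 100%,
    red below) is rendered alongside.
    """
    required = {"variant"}
    if not required <= set(fits.columns):
        raise ValueError(f"fits table must have columns {sorted(required)}")
    table = normalize_to_reference(fits, reference_id=reference_id)
    if sort and {"loop_length", "del_start"} <= set(table.columns):
        is_ref = (table["variant"] == reference_id).astype(int)
        table = (
            table.assign(_ref=is_ref)
            .sort_values(
                ["_ref", "loop_length", "del_start"],
                ascending=[False, False, True],
            )
            .drop(columns="_ref")
            .reset_index(drop=True)
        )
    if figure_path is not None:
        _render_heatmap(table, Path(figure_path))
    return table


def _render_heatmap(table: pd.DataFrame, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import LogNorm

    pct_cols = [c for c in table.columns if c.startswith("pct_")
                and c != "pct_ki_inverse"]
    if not pct_cols:
        return
    data = table[pct_cols].to_numpy(dtype=float)
    data = np.clip(data, 1e-2, None)
    fig, ax = plt.subplots(
        figsize=(2 + 1.2 * len(pct_cols), 1 + 0.25 * len(table))
    )
    im = ax.imshow(
        data, aspect="auto", cmap="RdBu",
        norm=LogNorm(vmin=10, vmax=1000),
    )
    ax.set_xticks(range(len(pct_cols)), pct_cols, rotation=30, ha="right")
    ax.set_yticks(range(len(table)), table["variant"].astype(str))
    fig.colorbar(im, ax=ax, label="% of reference (log scale)")
    ax.set_title("Variant characterisation vs. reference")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
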