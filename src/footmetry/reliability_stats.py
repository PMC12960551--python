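"""Two-way ANOVA mean squares, absolute-agreement single-rater ICC with a
95% F-based confidence interval, reliability classification, and the
closed-form ICC sample-size calculation.

The intra-user design is tagged ``mixed`` and the inter-user design
``random``; both share the absolute-agreement single-measure point estimate
and interval, so the model tag is reporting metadata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateVarianceError, InvalidDesignError, MissingCellError

__all__ = [
    "RatingTable",
    "MeanSquares",
    "ICCResult",
    "SampleSizeSpec",
    "anova_mean_squares",
    "icc_agreement_single",
    "classify_icc",
    "icc_sample_size",
    "reliability_table",
    "read_panel",
    "write_panel",
    "PANEL_COLUMNS",
]

PANEL_COLUMNS = ("subject", "rater", "repetition", "condition", "measurement", "value")


@dataclass
class RatingTable:
    """Subjects x columns measurement matrix (columns = raters or repeats)."""

    values: np.ndarray
    label: str = ""

    def __post_init__(self):
        x = np.asarray(self.values, dtype=np.float64)
        if x.ndim != 2:
            raise InvalidDesignError("rating table must be 2-D")
        n, k = x.shape
        if n < 2 or k < 2:
            raise InvalidDesignError(f"rating table needs n>=2 and k>=2, got {n}x{k}")
        if not np.all(np.isfinite(x)):
            raise InvalidDesignError("rating table contains non-finite values")
        self.values = x

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class MeanSquares:
    """Two-way crossed ANOVA decomposition without replication."""

    msr: float  # between-subjects (rows)
    msc: float  # between-columns (raters/repeats)
    mse: float  # residual
    df_rows: int
    df_cols: int
    df_error: int
    n: int
    k: int
    total_ss: float

    @property
    def degenerate(self) -> bool:
        """True when the table is constant (ICC undefined)."""
        return self.total_ss <= 1e-12 * self.n * self.k


@dataclass(frozen=True)
class ICCResult:
    estimate: float
    ci_low: float
    ci_high: float
    model: str  # "random" | "mixed"
    form: str = "absolute-agreement,single-rater"
    alpha: float = 0.05
    n: int = 0
    k: int = 0


@dataclass(frozen=True)
class SampleSizeSpec:
    """Inputs to the ICC sample-size closed form."""

    rho0: float
    rho1: float
    k: int = 2
    alpha: float = 0.05
    power: float = 0.80

    def validate(self) -> None:
        if not (0.0 < self.rho0 < 1.0 and 0.0 < self.rho1 < 1.0):
            raise InvalidDesignError("rho0 and rho1 must lie in (0, 1)")
        if self.rho1 <= self.rho0:
            raise InvalidDesignError("expected reliability rho1 must exceed rho0")
        if self.k < 2:
            raise InvalidDesignError("k must be at least 2")
        if not (0.0 < self.alpha < 1.0 and 0.0 < self.power < 1.0):
            raise InvalidDesignError("alpha and power must lie in (0, 1)")


def _as_matrix(table) -> np.ndarray:
    if isinstance(table, RatingTable):
        return table.values
    return RatingTable(np.asarray(table, dtype=np.float64)).values


def anova_mean_squares(table) -> MeanSquares:
    """Standard two-way crossed ANOVA without replication.

    SSR + SSC + SSE equals the total sum of squares by construction.
    """
    x = _as_matrix(table)
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * float(((row_means - grand) ** 2).sum())
    ssc = n * float(((col_means - grand) ** 2).sum())
    sst = float(((x - grand) ** 2).sum())
    sse = max(sst - ssr - ssc, 0.0)
    # snap components that are pure floating-point residue to zero
    snap = 1e-11 * sst
    ssc = 0.0 if ssc < snap else ssc
    sse = 0.0 if sse < snap else sse
    return MeanSquares(
        msr=ssr / (n - 1),
        msc=ssc / (k - 1),
        mse=sse / ((n - 1) * (k - 1)),
        df_rows=n - 1,
        df_cols=k - 1,
        df_error=(n - 1) * (k - 1),
        n=n,
        k=k,
        total_ss=sst,
    )


def icc_agreement_single(
    table, model: str = "random", alpha: float = 0.05
) -> ICCResult:
    """Absolute-agreement single-rater ICC with an F-based CI.

    Point estimate: (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE)).
    The confidence interval uses the F-based construction with a
    Satterthwaite-approximated denominator degrees of freedom.
    """
    if model not in ("random", "mixed"):
        raise InvalidDesignError(f"model must be random|mixed, got {model!r}")
    ms = anova_mean_squares(table)
    if ms.degenerate:
        raise DegenerateVarianceError("constant rating table; ICC undefined")
    n, k = ms.n, ms.k
    msr, msc, mse = ms.msr, ms.msc, ms.mse
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom <= 0:
        raise DegenerateVarianceError("ICC denominator is non-positive")
    est = (msr - mse) / denom
    est = min(est, 1.0)

    if est >= 1.0 - 1e-12 and mse <= 1e-12 * max(1.0, msr) and msc <= 1e-12 * max(1.0, msr):
        lo = hi = 1.0
    else:
        a = (k * est) / (n * (1.0 - est)) if est < 1.0 else np.inf
        b = 1.0 + (k * est * (n - 1)) / (n * (1.0 - est)) if est < 1.0 else np.inf
        num_v = (a * msc + b * mse) ** 2
        den_v = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        v = num_v / den_v if den_v > 0 else (n - 1) * (k - 1)
        v = max(v, 1.0)
        f_low = stats.f.ppf(1.0 - alpha / 2.0, n - 1, v)
        f_up = stats.f.ppf(1.0 - alpha / 2.0, v, n - 1)
        lo = (
            n * (msr - f_low * mse)
            / (f_low * (k * msc + (k * n - k - n) * mse) + n * msr)
        )
        hi = (
            n * (f_up * msr - mse)
            / (k * msc + (k * n - k - n) * mse + n * f_up * msr)
        )
        lo = min(lo, est)
        hi = min(max(hi, est), 1.0)
    return ICCResult(
        estimate=float(est),
        ci_low=float(lo),
        ci_high=float(hi),
        model=model,
        alpha=alpha,
        n=n,
        k=k,
    )


def classify_icc(estimate: float) -> str:
    """Reliability band: poor < 0.5 <= moderate < 0.75 <= good < 0.9 <= excellent."""
    if estimate > 1.0:
        raise InvalidDesignError(f"ICC estimate cannot exceed 1, got {estimate}")
    if estimate < 0.5:
        return "poor"
    if estimate < 0.75:
        return "moderate"
    if estimate < 0.9:
        return "good"
    return "excellent"


def icc_sample_size(spec: Optional[SampleSizeSpec] = None, **kwargs) -> int:
    """Minimum subject count for an ICC reliability study (closed form).

    n = 1 + 2 k (z_{1-a/2} + z_{power})^2 / [(k-1) (ln C0)^2] with
    C0 = (1 + k rho0/(1-rho0)) / (1 + k rho1/(1-rho1)), rounded up.
    """
    if spec is None:
        spec = SampleSizeSpec(**kwargs)
    spec.validate()
    k = spec.k
    c0 = (1.0 + k * spec.rho0 / (1.0 - spec.rho0)) / (
        1.0 + k * spec.rho1 / (1.0 - spec.rho1)
    )
    z_a = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    z_b = stats.norm.ppf(spec.power)
    n = 1.0 + 2.0 * k * (z_a + z_b) ** 2 / ((k - 1) * math.log(c0) ** 2)
    return int(math.ceil(n - 1e-9))


# ---------------------------------------------------------------------------
# panel handling
# ---------------------------------------------------------------------------


def _check_panel(panel: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PANEL_COLUMNS if c not in panel.columns]
    if missing:
        raise InvalidDesignError(f"panel missing columns: {missing}")
    return panel


def _pivot_complete(
    sub: pd.DataFrame, columns: str, label: str
) -> np.ndarray:
    wide = sub.pivot_table(
        index="subject", columns=columns, values="value", aggfunc="first"
    )
    if wide.isna().any().any():
        cells = [
            f"{label}/subject={idx}/{columns}={col}"
            for idx, row in wide.iterrows()
            for col, bad in row.isna().items()
            if bad
        ]
        raise MissingCellError(cells)
    return wide.to_numpy()


def reliability_table(
    panel: pd.DataFrame,
    mode: str = "inter",
    alpha: float = 0.05,
    rater: Optional[str] = None,
    repetition: Optional[object] = None,
    measurements: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per-measurement, per-condition ICC results from a long-format panel.

    ``mode='intra'`` analyses the repetitions of a single rater with the
    mixed-model tag; ``mode='inter'`` analyses one repetition across raters
    with the random-model tag.  Incomplete designs raise
    :class:`MissingCellError` naming the absent cells.
    """
    panel = _check_panel(panel)
    if mode not in ("intra", "inter"):
        raise InvalidDesignError(f"mode must be intra|inter, got {mode!r}")
    rows = []
    conditions = sorted(panel["condition"].unique())
    names: Iterable[str] = (
        measurements if measurements is not None else sorted(panel["measurement"].unique())
    )
    for condition in conditions:
        cpanel = panel[panel["condition"] == condition]
        if mode == "intra":
            who = rater if rater is not None else sorted(cpanel["rater"].unique())[0]
            sel = cpanel[cpanel["rater"] == who]
            columns, model = "repetition", "mixed"
        else:
            rep = (
                repetition
                if repetition is not None
                else sorted(cpanel["repetition"].unique())[0]
            )
            sel = cpanel[cpanel["repetition"] == rep]
            columns, model = "rater", "random"
        for name in names:
            sub = sel[sel["measurement"] == name]
            label = f"{name}/{condition}"
            matrix = _pivot_complete(sub, columns, label)
            res = icc_agreement_single(matrix, model=model, alpha=alpha)
            rows.append(
                {
                    "condition": condition,
                    "measurement": name,
                    "model": model,
                    "icc": res.estimate,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "classification": classify_icc(res.estimate),
                    "n": res.n,
                    "k": res.k,
                }
            )
    return pd.DataFrame(rows)


def read_panel(path) -> pd.DataFrame:
    """Read a long-format rating panel CSV."""
    panel = pd.read_csv(path)
    return _check_panel(panel)


def write_panel(panel: pd.DataFrame, path) -> None:
    _check_panel(panel).to_csv(path, index=False)
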