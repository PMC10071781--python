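"""Agreement statistics between two SUVR measurement methods.

The battery mirrors how template-space quantification is validated
against an individual-space parcellation reference: per-region ordinary
least squares of the test method on the reference (slope, intercept, R²),
two-way mixed-effects single-measure consistency intraclass correlation
ICC(3,1), and Bland-Altman bias with 95% limits of agreement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

from .quantification import COMPOSITE_NAMES, SUVRReport, reports_to_frame

__all__ = [
    "PairedMeasurements", "RegressionResult", "ICCResult", "BlandAltmanResult",
    "pearson_regression", "icc_consistency", "bland_altman", "compare_methods",
    "plot_agreement",
]

LOA_MULTIPLIER = 1.96  # 95% limits of agreement


@dataclass
class PairedMeasurements:
    """Paired SUVRs for one region: ``x`` reference method, ``y`` test method."""

    subject_ids: list[str]
    x: np.ndarray
    y: np.ndarray
    region: str = ""

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        if not (len(self.subject_ids) == len(self.x) == len(self.y)):
            raise ValueError("subject_ids, x and y must have equal length")
        if len(self.x) < 3:
            raise ValueError("need at least 3 paired measurements")
        for name, v in (("x", self.x), ("y", self.y)):
            if not np.isfinite(v).all() or (v <= 0).any():
                raise ValueError(f"{name} must be finite and positive")

    @property
    def n(self) -> int:
        return len(self.x)


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    n: int


@dataclass
class ICCResult:
    icc: float
    model: str = "ICC(3,1) two-way mixed, single measure, consistency"


@dataclass
class BlandAltmanResult:
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n: int


def pearson_regression(pairs: PairedMeasurements) -> RegressionResult:
    """OLS of y on x; R² is the squared Pearson correlation."""
    if np.var(pairs.x) == 0:
        raise ValueError("x has zero variance; regression undefined")
    fit = stats.linregress(pairs.x, pairs.y)
    return RegressionResult(slope=float(fit.slope), intercept=float(fit.intercept),
                            r_squared=float(fit.rvalue ** 2), n=pairs.n)


def icc_consistency(pairs: PairedMeasurements) -> ICCResult:
    """ICC(3,1): (MS_subjects − MS_error)/(MS_subjects + MS_error) for 2 raters.

    The consistency form is invariant to a fixed offset between the two
    methods. Degenerate data (no between-subject variance at all) is
    rejected.
    """
    if np.var(pairs.x) == 0 and np.var(pairs.y) == 0:
        raise ValueError("all measurements identical; ICC undefined")
    long = pd.DataFrame({
        "subject": list(pairs.subject_ids) * 2,
        "rater": ["x"] * pairs.n + ["y"] * pairs.n,
        "value": np.concatenate([pairs.x, pairs.y]),
    })
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # perfect agreement gives MS_error = 0; pingouin's F/CI internals
        # divide by it but the ICC point estimate is still well-defined
        warnings.simplefilter("ignore", RuntimeWarning)
        table = pg.intraclass_corr(data=long, targets="subject", raters="rater",
                                   ratings="value")
    # ICC(C,1): single-measure consistency, i.e. ICC(3,1) for fixed raters
    icc3 = table.loc[table["Type"] == "ICC(C,1)", "ICC"].iloc[0]
    return ICCResult(icc=float(icc3))


def bland_altman(pairs: PairedMeasurements) -> BlandAltmanResult:
    """Bias (mean of y−x) and bias ± 1.96·SD limits (sample SD, n−1)."""
    if pairs.n < 2:
        raise ValueError("need at least 2 pairs")
    d = pairs.y - pairs.x
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(bias=bias, sd_diff=sd,
                             loa_low=bias - LOA_MULTIPLIER * sd,
                             loa_high=bias + LOA_MULTIPLIER * sd, n=pairs.n)


def compare_methods(reports_x: list[SUVRReport],
                    reports_y: list[SUVRReport]) -> pd.DataFrame:
    """Join two report collections by subject and region and analyze each region.

    Returns one row per composite region with slope, intercept, R², ICC,
    bias and limits of agreement. Regions with fewer than 3 common
    subjects are flagged (``flagged=True``, statistics NaN) rather than
    computed.
    """
    fx = reports_to_frame(reports_x)
    fy = reports_to_frame(reports_y)
    merged = fx.merge(fy, on=["subject_id", "region"], suffixes=("_x", "_y"))
    rows = []
    for region in COMPOSITE_NAMES:
        sub = merged[merged["region"] == region]
        row = {"region": region, "n": len(sub), "flagged": False}
        if len(sub) < 3:
            row.update({"flagged": True, "slope": np.nan, "intercept": np.nan,
                        "r_squared": np.nan, "icc": np.nan, "bias": np.nan,
                        "loa_low": np.nan, "loa_high": np.nan})
            rows.append(row)
            continue
        pairs = PairedMeasurements(subject_ids=list(sub["subject_id"]),
                                   x=sub["suvr_x"].to_numpy(),
                                   y=sub["suvr_y"].to_numpy(), region=region)
        reg = pearson_regression(pairs)
        icc = icc_consistency(pairs)
        ba = bland_altman(pairs)
        row.update({"slope": reg.slope, "intercept": reg.intercept,
                    "r_squared": reg.r_squared, "icc": icc.icc,
                    "bias": ba.bias, "loa_low": ba.loa_low, "loa_high": ba.loa_high})
        rows.append(row)
    return pd.DataFrame(rows, columns=["region", "n", "flagged", "slope", "intercept",
                                       "r_squared", "icc", "bias", "loa_low", "loa_high"])


def plot_agreement(pairs: PairedMeasurements, path=None):
    """Scatter + identity/fit lines and a Bland-Altman panel (one region)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    reg = pearson_regression(pairs)
    ba = bland_altman(pairs)
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    ax1.scatter(pairs.x, pairs.y, s=18, alpha=0.8)
    lim = [min(pairs.x.min(), pairs.y.min()), max(pairs.x.max(), pairs.y.max())]
    ax1.plot(lim, lim, "k--", lw=1, label="identity")
    xs = np.linspace(lim[0], lim[1], 10)
    ax1.plot(xs, reg.slope * xs + reg.intercept, "b-", lw=1,
             label=f"fit: y={reg.slope:.3f}x+{reg.intercept:.3f}")
    ax1.set_xlabel("reference SUVR")
    ax1.set_ylabel("test SUVR")
    ax1.set_title(pairs.region or "SUVR agreement")
    ax1.legend(fontsize=8)
    mean = (pairs.x + pairs.y) / 2
    ax2.scatter(mean, pairs.y - pairs.x, s=18, alpha=0.8)
    for y, style in ((ba.bias, "b-"), (ba.loa_low, "k--"), (ba.loa_high, "k--")):
        ax2.axhline(y, ls=style[1:], color=style[0], lw=1)
    ax2.set_xlabel("mean SUVR")
    ax2.set_ylabel("difference (test − reference)")
    ax2.set_title(f"bias {ba.bias:+.3f} [{ba.loa_low:+.3f}, {ba.loa_high:+.3f}]")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
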