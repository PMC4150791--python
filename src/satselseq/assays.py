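"""Downstream biochemical quantifications.

Three independent assay reductions: sequence-preference profiles from the
16-substrate XXC deamination panel (X = A, 5-methylcytosine, G or T at the
-2 and -1 positions flanking the target cytosine), fluctuation mutation
frequencies from rifampin-resistance colony counts, and Michaelis-Menten
kinetics fitted to substrate-concentration/rate series.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

#: Context symbols of the XXC panel; 5-methylcytosine is spelled "mC".
PANEL_SYMBOLS: tuple[str, ...] = ("A", "mC", "G", "T")


@dataclass(frozen=True)
class PreferenceProfile:
    """Relative reactivity by flanking nucleotide (each position sums to 1)."""

    minus1: dict[str, float]
    minus2: dict[str, float]

    def to_dict(self) -> dict:
        return {"minus1": dict(self.minus1), "minus2": dict(self.minus2)}


def _validate_panel(panel: pd.DataFrame) -> pd.DataFrame:
    required = {"x2", "x1", "product_fraction"}
    if not required.issubset(panel.columns):
        raise ValueError(f"panel needs columns {sorted(required)}")
    seen = set(zip(panel["x2"], panel["x1"]))
    expected = set(itertools.product(PANEL_SYMBOLS, PANEL_SYMBOLS))
    missing = sorted(expected - seen)
    if missing or len(panel) != 16:
        raise ValueError(f"panel must contain each of the 16 (x2, x1) contexts once; missing {missing}")
    return panel


def preference_profile(panel: pd.DataFrame) -> PreferenceProfile:
    """Average product formation by shared -1 / -2 nucleotide, normalized.

    For position k and symbol X, the mean product fraction over the four
    substrates carrying X at k is divided by the sum of the four means, so
    each position's reactivities sum to 1. Invariant to uniform rescaling
    of all product fractions.
    """
    panel = _validate_panel(panel)

    def profile(col: str) -> dict[str, float]:
        means = panel.groupby(col)["product_fraction"].mean()
        means = means.reindex(PANEL_SYMBOLS)
        total = means.sum()
        if total <= 0:
            raise ValueError("no product formation in panel")
        return {sym: float(means[sym] / total) for sym in PANEL_SYMBOLS}

    return PreferenceProfile(minus1=profile("x1"), minus2=profile("x2"))


@dataclass(frozen=True)
class FluctuationSummary:
    """Per-culture mutation frequencies with mean and sample SD."""

    frequencies: tuple[float, ...]
    mean: float
    sd: float
    label: str = ""

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "frequencies": list(self.frequencies),
            "mean": self.mean,
            "sd": self.sd,
            "n_cultures": len(self.frequencies),
        }


def mutation_frequency(cultures: pd.DataFrame, label: str = "") -> FluctuationSummary:
    """Mutation frequency per culture: resistant colonies / viable cells.

    Expects columns ``resistant`` and ``viable``; the summary reports the
    across-culture mean and sample standard deviation (ddof=1; SD is 0 for
    a single culture). This is a frequency, not a Luria-Delbruck rate.
    """
    if len(cultures) < 1:
        raise ValueError("need at least one culture")
    if (cultures["viable"] <= 0).any():
        raise ValueError("viable cell counts must be positive")
    if (cultures["resistant"] < 0).any():
        raise ValueError("resistant colony counts must be non-negative")
    freqs = (cultures["resistant"] / cultures["viable"]).to_numpy(float)
    sd = float(np.std(freqs, ddof=1)) if len(freqs) > 1 else 0.0
    return FluctuationSummary(tuple(float(f) for f in freqs), float(freqs.mean()), sd, label)


def compare_mutators(
    exp_a: FluctuationSummary,
    exp_b: FluctuationSummary,
    floor: float = 1e-9,
) -> dict:
    """Fold change of mean frequencies and a two-sided Welch t-test p-value.

    The test runs on log10(frequency + floor), since fluctuation
    frequencies are right-skewed; with an all-zero group the log scale is
    degenerate and a Mann-Whitney rank test is used instead (warned).
    """
    if len(exp_a.frequencies) < 3 or len(exp_b.frequencies) < 3:
        raise ValueError("need at least 3 cultures per group")
    a, b = np.asarray(exp_a.frequencies), np.asarray(exp_b.frequencies)
    fold = exp_a.mean / exp_b.mean if exp_b.mean > 0 else np.inf
    if a.max() == 0 or b.max() == 0:
        warnings.warn("all-zero group; falling back to rank test", stacklevel=2)
        result = stats.mannwhitneyu(a, b, alternative="two-sided")
        test = "mannwhitneyu"
    else:
        result = stats.ttest_ind(np.log10(a + floor), np.log10(b + floor), equal_var=False)
        test = "welch_t_log10"
    return {"fold_change": float(fold), "p_value": float(result.pvalue), "test": test}


@dataclass(frozen=True)
class KineticFit:
    """Michaelis-Menten fit results: estimates, SEs, residuals."""

    vmax: float
    km: float
    vmax_se: float
    km_se: float
    rss: float
    n_points: int

    def rate(self, s) -> np.ndarray:
        """Fitted curve v(S) = Vmax·S / (Km + S)."""
        s = np.asarray(s, dtype=float)
        return self.vmax * s / (self.km + s)

    def summary(self) -> str:
        return (
            f"Michaelis-Menten fit (n={self.n_points})\n"
            f"  Vmax = {self.vmax:.6g} +/- {self.vmax_se:.3g}\n"
            f"  Km   = {self.km:.6g} +/- {self.km_se:.3g}\n"
            f"  RSS  = {self.rss:.6g}"
        )

    def to_dict(self) -> dict:
        return {
            "vmax": self.vmax, "km": self.km,
            "vmax_se": self.vmax_se, "km_se": self.km_se,
            "rss": self.rss, "n_points": self.n_points,
        }


def _mm(s, vmax, km):
    return vmax * s / (km + s)


def fit_michaelis_menten(concentrations, rates) -> KineticFit:
    """Least-squares Michaelis-Menten fit v = Vmax·S/(Km+S).

    Initial guesses: Vmax0 = max observed rate, Km0 = concentration whose
    rate is nearest half-maximal; parameters are bounded positive
    (trust-region least squares). Standard errors come from the Jacobian
    covariance.
    """
    s = np.asarray(concentrations, dtype=float)
    v = np.asarray(rates, dtype=float)
    if len(np.unique(s)) < 3:
        raise ValueError("need at least 3 distinct substrate concentrations")
    if np.allclose(v, v[0]):
        raise ValueError("rates are all equal; Km is unidentifiable")
    if (s < 0).any() or (v < 0).any():
        raise ValueError("concentrations and rates must be non-negative")
    vmax0 = float(v.max())
    km0 = float(s[np.argmin(np.abs(v - vmax0 / 2))])
    km0 = max(km0, 1e-12)
    try:
        popt, pcov = optimize.curve_fit(
            _mm, s, v, p0=[vmax0, km0], bounds=([0, 0], [np.inf, np.inf]), maxfev=10_000
        )
    except RuntimeError as exc:
        raise RuntimeError(f"Michaelis-Menten fit did not converge: {exc}") from exc
    residuals = v - _mm(s, *popt)
    se = np.sqrt(np.diag(pcov))
    return KineticFit(
        vmax=float(popt[0]), km=float(popt[1]),
        vmax_se=float(se[0]), km_se=float(se[1]),
        rss=float(residuals @ residuals), n_points=len(s),
    )


# TSV readers for the documented assay input formats ------------------------

def read_panel_tsv(path) -> pd.DataFrame:
    return _validate_panel(pd.read_csv(path, sep="\t"))


def read_fluctuation_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"resistant", "viable"}.issubset(df.columns):
        raise ValueError("fluctuation table needs columns resistant, viable")
    return df


def read_kinetics_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"conc_nM", "rate"}.issubset(df.columns):
        raise ValueError("kinetics table needs columns conc_nM, rate")
    return df
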