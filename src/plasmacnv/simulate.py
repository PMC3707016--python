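"""Detection-limit simulation: synthetic cohorts, in-silico dilution and ROC.

Artificial controls are drawn per window from Normal(mean_i, SD_i) using the
per-window mean and SD of a healthy-control cohort (truncated at zero, since
read-count ratios cannot be negative).  A tumor case is the same draw with
the mean multiplied by the diluted copy-number ratio

    1 - lambda + lambda * ratio_segment

where lambda is the fraction of tumor DNA.  Cases and controls are scored
with the genome-wide z-score (cross-validated control S baseline) and swept
through an ROC analysis to locate the detection limit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import zscores


@dataclass
class TumorProfile:
    """Per-window copy-number ratio (1 = diploid), expanded to the window grid."""

    ratio: np.ndarray
    label: str = "tumor"

    def __post_init__(self):
        self.ratio = np.asarray(self.ratio, float)
        if (self.ratio < 0).any():
            raise ValueError("copy-number ratios must be >= 0")


@dataclass
class RocResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    threshold: float  # Youden operating point
    op_sensitivity: float
    op_specificity: float


def counting_noise_sd(n_reads: int, n_windows: int, overdispersion: float = 1.0) -> float:
    """Per-window ratio SD implied by Poisson counting at the given depth.

    With N reads over m equal windows the expected count is N/m, so the
    count ratio has coefficient of variation sqrt(m/N); ``overdispersion``
    scales it for extra technical variance.
    """
    return overdispersion * float(np.sqrt(n_windows / n_reads))


def dilute(tumor: TumorProfile | np.ndarray, lam: float) -> np.ndarray:
    """Diluted expected ratio 1 - lam + lam * ratio (affine in lam)."""
    if not 0 <= lam <= 1:
        raise ValueError("lambda must be in [0, 1]")
    ratio = tumor.ratio if isinstance(tumor, TumorProfile) else np.asarray(tumor, float)
    return 1.0 - lam + lam * ratio


def simulate_control(
    mean: np.ndarray, sd: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One control ratio profile ~ Normal(mean, sd), truncated at 0."""
    mean = np.asarray(mean, float)
    sd = np.asarray(sd, float)
    if (sd < 0).any():
        raise ValueError("SDs must be >= 0")
    return np.clip(rng.normal(mean, sd), 0.0, None)


def simulate_case(
    tumor: TumorProfile | np.ndarray,
    lam: float,
    mean: np.ndarray,
    sd: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """One case profile: the control model with its mean scaled by the diluted ratio."""
    scaled = np.asarray(mean, float) * dilute(tumor, lam)
    return np.clip(rng.normal(scaled, np.asarray(sd, float)), 0.0, None)


def simulate_cohort(
    mean: np.ndarray, sd: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """n control profiles as rows."""
    return np.vstack([simulate_control(mean, sd, rng) for _ in range(n)])


def roc(case_scores: np.ndarray, control_scores: np.ndarray) -> RocResult:
    """ROC over all score thresholds; a case is called when score >= threshold.

    AUC equals the Mann-Whitney pair statistic (ties get half credit).  The
    operating point maximizes the Youden index, ties resolved toward higher
    specificity.
    """
    cases = np.asarray(case_scores, float)
    controls = np.asarray(control_scores, float)
    if cases.size == 0 or controls.size == 0:
        raise ValueError("both score sets must be non-empty")
    thresholds = np.unique(np.concatenate([cases, controls]))[::-1]
    sens = (cases[None, :] >= thresholds[:, None]).mean(axis=1)
    spec = (controls[None, :] < thresholds[:, None]).mean(axis=1)
    gt = (cases[None, :] > controls[:, None]).sum()
    eq = (cases[None, :] == controls[:, None]).sum()
    auc = (gt + 0.5 * eq) / (cases.size * controls.size)
    youden = sens + spec - 1.0
    best = youden.max()
    # among ties, the highest threshold gives the highest specificity
    pick = int(np.flatnonzero(youden == best)[0])
    return RocResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=float(auc),
        threshold=float(thresholds[pick]),
        op_sensitivity=float(sens[pick]),
        op_specificity=float(spec[pick]),
    )


def detection_limit(
    tumor_profiles: list[TumorProfile],
    lambdas: list[float],
    n_controls: int,
    mean: np.ndarray,
    sd: np.ndarray,
    seed: int | None = None,
) -> pd.DataFrame:
    """Sensitivity/specificity/AUC of the genome-wide z over a dilution grid.

    For each lambda one case per tumor profile and ``n_controls`` controls
    are simulated.  The controls form the scoring cohort: each control's
    per-window z is computed leave-one-out and its S standardized against the
    cohort's cross-validated S values; cases are scored against the full
    cohort with the same S baseline.  Cross-validation inflates the control
    score spread slightly, so the ROC is, if anything, conservative.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for lam in lambdas:
        cohort = simulate_cohort(mean, sd, n_controls, rng)
        cases = np.vstack(
            [simulate_case(t, lam, mean, sd, rng) for t in tumor_profiles]
        )
        control_s = zscores.cohort_s_scores(cohort)
        s_mean, s_sd = float(np.mean(control_s)), float(np.std(control_s, ddof=1))
        control_scores = (control_s - s_mean) / s_sd
        case_scores = zscores.genome_wide_scores(cases, cohort)
        r = roc(case_scores, control_scores)
        rows.append(
            {
                "lambda": lam,
                "auc": r.auc,
                "sensitivity": r.op_sensitivity,
                "specificity": r.op_specificity,
                "threshold": r.threshold,
                "n_cases": len(tumor_profiles),
                "n_controls": n_controls,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Synthetic tumor profiles
# ---------------------------------------------------------------------------


def profile_from_segments(
    segments: list[tuple[float, float, float]], n_windows: int, label: str = "tumor"
) -> TumorProfile:
    """Build a window-level profile from (start_frac, end_frac, ratio) segments."""
    ratio = np.ones(n_windows)
    for start, end, value in segments:
        ratio[int(start * n_windows) : int(end * n_windows)] = value
    return TumorProfile(ratio, label=label)


def prostate_like_profile(
    n_windows: int, rng: np.random.Generator, label: str = "prostate"
) -> TumorProfile:
    """A prostate-cancer-like profile: 8p-type loss, 8q-type gain, AR-type gain.

    Segment placement and amplitudes are jittered so a cohort of profiles is
    heterogeneous, as empirical tumor collections are.
    """
    ratio = np.ones(n_windows)

    def place(frac_len, value):
        length = max(2, int(frac_len * n_windows))
        start = int(rng.integers(0, n_windows - length))
        ratio[start : start + length] = value

    place(0.08, rng.uniform(0.4, 0.6))  # arm-level loss (8p-like)
    place(0.10, rng.uniform(1.4, 1.7))  # arm-level gain (8q-like)
    place(0.02, rng.uniform(1.8, 2.8))  # focal amplification (AR-like)
    place(0.01, rng.uniform(0.2, 0.6))  # focal deletion (3-Mbp-scale)
    return TumorProfile(ratio, label=label)


def aggressive_profile(n_windows: int, label: str = "cellline") -> TumorProfile:
    """A heavily aberrant cell-line-like profile with high-amplitude changes.

    Roughly 15% of the genome at ratio 3, 15% gained at 1.5, 10% near-
    homozygously lost and 10% single-copy lost, mimicking a grossly
    aneuploid colorectal cancer line.
    """
    segs = [
        (0.05, 0.20, 3.0),
        (0.30, 0.45, 1.5),
        (0.55, 0.65, 0.25),
        (0.80, 0.90, 0.5),
    ]
    return profile_from_segments(segs, n_windows, label=label)
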