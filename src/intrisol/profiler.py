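"""pH 0-12 solubility profiles from intrinsic solubility and pKa's.

At each grid pH the relevant pKa subset is identified; when more than three
pKa's would impact solubility the point is marked undetermined rather than
extrapolated.  Because ``log S(pH) = log S0 + log Phi(pH)`` is linear in
``log S0`` for fixed pKa's, two profiles of the same compound differ by a
constant offset equal to their S0 difference — a prediction error in S0
translates into a uniform vertical shift of the whole profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .speciation import (
    DEFAULT_FRACTION_THRESHOLD,
    MAX_RELEVANT_PKAS,
    IonizationModel,
    relevant_pkas,
    solubility_at_ph,
)
from .evalsplit import rmse

__all__ = [
    "SolubilityProfile",
    "compute_profile",
    "profile_offset",
    "evaluate_profiles",
    "ProfileEvaluation",
]


@dataclass
class SolubilityProfile:
    ph_grid: np.ndarray       # ascending, within [0, 12]
    log_s: np.ndarray         # log10 molar; NaN where undetermined
    undetermined: np.ndarray  # bool mask
    log_s0: float
    model: IonizationModel

    def to_frame(self, compound_id: str = "") -> pd.DataFrame:
        df = pd.DataFrame({
            "ph": self.ph_grid,
            # undetermined points serialize as empty fields, not sentinels
            "log_s": [("" if u else v) for v, u in
                      zip(self.log_s, self.undetermined)],
            "undetermined": self.undetermined.astype(int),
        })
        if compound_id:
            df.insert(0, "compound_id", compound_id)
        return df


def compute_profile(
    log_s0: float,
    model: IonizationModel,
    grid_step: float = 0.1,
    ph_min: float = 0.0,
    ph_max: float = 12.0,
    fraction_threshold: float = DEFAULT_FRACTION_THRESHOLD,
) -> SolubilityProfile:
    """Evaluate log S over an evenly spaced pH grid.

    Points where more than MAX_RELEVANT_PKAS pKa's are relevant are flagged
    undetermined and carry NaN.
    """
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    n = int(round((ph_max - ph_min) / grid_step))
    grid = ph_min + grid_step * np.arange(n + 1)
    log_s = np.full(len(grid), np.nan)
    und = np.zeros(len(grid), bool)
    for i, ph in enumerate(grid):
        sub, n_rel = relevant_pkas(model, ph, fraction_threshold)
        if n_rel > MAX_RELEVANT_PKAS:
            und[i] = True
            continue
        log_s[i] = solubility_at_ph(log_s0, sub, ph)
    return SolubilityProfile(
        ph_grid=grid, log_s=log_s, undetermined=und,
        log_s0=log_s0, model=model,
    )


def profile_offset(
    profile_a: SolubilityProfile, profile_b: SolubilityProfile
) -> tuple[float, float]:
    """Mean offset between two profiles and max deviation from constancy.

    Both profiles must share the grid and the ionization model; the offset is
    evaluated over the jointly determined points.  Returns
    ``(mean_offset, max |difference - mean_offset|)``.
    """
    if not np.allclose(profile_a.ph_grid, profile_b.ph_grid):
        raise ValueError("profiles must share the pH grid")
    if profile_a.model != profile_b.model:
        raise ValueError("profiles must share the ionization model")
    joint = ~(profile_a.undetermined | profile_b.undetermined)
    if not joint.any():
        raise ValueError("no jointly determined pH points")
    diff = profile_a.log_s[joint] - profile_b.log_s[joint]
    mean = float(diff.mean())
    return mean, float(np.max(np.abs(diff - mean)))


@dataclass
class ProfileEvaluation:
    """Cohort comparison of predicted vs measurement-derived S0 profiles."""

    per_compound: pd.DataFrame   # compound_id, s0_derived, s0_predicted, abs_error
    rmse: float
    q75_error: float             # 75th percentile of |error|
    frac_below_q75: float

    def pairs(self, grid_step: float = 0.1):
        """Yield (compound_id, derived profile, predicted profile) for plotting."""
        for _, row in self.per_compound.iterrows():
            model = row["model"]
            yield (
                row["compound_id"],
                compute_profile(row["s0_derived"], model, grid_step),
                compute_profile(row["s0_predicted"], model, grid_step),
            )


def evaluate_profiles(
    compound_ids,
    s0_derived,
    s0_predicted,
    models: list[IonizationModel],
) -> ProfileEvaluation:
    """Per-compound S0 error statistics for a profile cohort.

    ``s0_derived`` are the measurement-derived values, ``s0_predicted`` the
    model's.  Because profiles shift rigidly with S0, the per-compound profile
    discrepancy equals the S0 error; the summary therefore reports the S0
    RMSE, the 75th-percentile absolute error, and the fraction of compounds
    below that quantile.
    """
    d = np.asarray(s0_derived, float)
    p = np.asarray(s0_predicted, float)
    if not (len(compound_ids) == len(d) == len(p) == len(models)):
        raise ValueError("inputs must align")
    err = np.abs(p - d)
    q75 = float(np.quantile(err, 0.75))
    df = pd.DataFrame({
        "compound_id": list(compound_ids),
        "s0_derived": d,
        "s0_predicted": p,
        "abs_error": err,
        "model": models,
    })
    return ProfileEvaluation(
        per_compound=df,
        rmse=rmse(d, p),
        q75_error=q75,
        frac_below_q75=float(np.mean(err <= q75)),
    )


def plot_profile_pair(compound_id, derived, predicted, measured_points=None,
                      ax=None):
    """Line plot of derived vs predicted profiles plus measured points."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    ax.plot(derived.ph_grid, derived.log_s, label="derived S0", color="C0")
    ax.plot(predicted.ph_grid, predicted.log_s, label="predicted S0",
            color="C1", linestyle="--")
    if measured_points:
        phs, vals = zip(*measured_points)
        ax.scatter(phs, vals, color="k", zorder=3, label="measured")
    ax.set_xlabel("pH")
    ax.set_ylabel("log S (molar)")
    ax.set_title(str(compound_id))
    ax.legend(fontsize=7)
    return ax
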