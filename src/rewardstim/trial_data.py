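"""Trial-table data model: TSV readers/writers, validation, disparity
normalization and the per-site inclusion filter.

One row per behavioural trial.  Disparities are signed in degrees of visual
angle, positive toward the PREF rotation direction of the stimulated site
(conversion from raw CW/CCW coding happens at load using the site's
``pref_direction``).  Zero-disparity trials are perceptually ambiguous: their
``correct`` field is undefined and encoded as NA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

TRIAL_COLUMNS = [
    "site_id",
    "animal_id",
    "trial_index",
    "disparity_deg",
    "microstim",
    "available_reward_ml",
    "reward_category",
    "choice_pref",
    "correct",
    "rewarded",
    "delta_dx",
]

SITE_COLUMNS = [
    "site_id",
    "animal_id",
    "pref_direction",
    "eccentricity_deg",
    "max_abs_disparity_deg",
    "disparity_levels",
]


class SchemaError(ValueError):
    """A required column is missing or malformed."""


class ValidationError(ValueError):
    """A row violates a trial-table invariant."""


@dataclass(frozen=True)
class SiteMeta:
    """Per-site descriptors needed for normalization and pooling."""

    site_id: str
    animal_id: str
    pref_direction: str  # "CW" or "CCW"
    eccentricity_deg: float
    max_abs_disparity_deg: float
    disparity_levels: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.pref_direction not in ("CW", "CCW"):
            raise ValueError("pref_direction must be 'CW' or 'CCW'")
        if self.max_abs_disparity_deg <= 0:
            raise ValueError("max_abs_disparity_deg must be > 0")
        if len(set(self.disparity_levels)) != len(self.disparity_levels):
            raise ValueError("disparity levels must be distinct")
        if self.disparity_levels and not np.isclose(
            max(abs(d) for d in self.disparity_levels), self.max_abs_disparity_deg
        ):
            raise ValueError("max(|disparity_levels|) must equal max_abs_disparity_deg")


def _require_columns(df: pd.DataFrame, columns: list[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing column(s): {', '.join(missing)}")


def validate_trials(trials: pd.DataFrame) -> None:
    """Check the trial-table invariants, naming the first offending row."""
    _require_columns(trials, TRIAL_COLUMNS, "trial table")
    d = trials["disparity_deg"].to_numpy(dtype=float)
    correct = trials["correct"]
    rewarded = trials["rewarded"].to_numpy(dtype=float)
    delta_dx = trials["delta_dx"].to_numpy(dtype=float)

    zero = d == 0.0
    bad = zero & correct.notna().to_numpy()
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ValidationError(f"row {trials.index[row]}: zero-disparity trial has defined 'correct'")
    bad = ~zero & correct.isna().to_numpy()
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ValidationError(f"row {trials.index[row]}: non-zero disparity trial has undefined 'correct'")

    # On ordinary (non-delta-dx) informative trials the payout tracks correctness.
    informative = ~zero & (delta_dx == 0)
    if informative.any():
        mism = informative & (correct.fillna(-1).to_numpy(dtype=float) != rewarded)
        if mism.any():
            row = int(np.flatnonzero(mism)[0])
            raise ValidationError(f"row {trials.index[row]}: rewarded != correct on a non-zero-disparity trial")

    for col in ("microstim", "choice_pref", "rewarded", "delta_dx"):
        vals = trials[col].to_numpy(dtype=float)
        if not np.isin(vals, (0.0, 1.0)).all():
            raise ValidationError(f"column {col!r} must be binary 0/1")

    if (trials["available_reward_ml"].to_numpy(dtype=float) < 0).any():
        raise ValidationError("available_reward_ml must be >= 0")
    cats = set(trials["reward_category"].unique())
    if not cats <= {"small", "large"}:
        raise ValidationError(f"reward_category must be 'small'/'large', got {sorted(cats)}")

    # Large reward means the animal's schedule maximum is at stake.
    for animal, sub in trials.groupby("animal_id"):
        vols = sub["available_reward_ml"].to_numpy(dtype=float)
        large = (sub["reward_category"] == "large").to_numpy()
        if large.any():
            vmax = vols.max()
            if not np.allclose(vols[large], vmax):
                raise ValidationError(f"animal {animal}: 'large' trials do not share the maximum volume")
            if large.size > large.sum() and (vols[~large] >= vmax - 1e-12).any():
                raise ValidationError(f"animal {animal}: 'small' trial at the maximum volume")


def load_trials(trials_path, sites_path=None) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Load (and validate) a trial table, optionally with its site metadata.

    Returns the trial table sorted by ``trial_index`` within site, and the
    site table (or None if no path was given).
    """
    trials = pd.read_csv(trials_path, sep="\t", dtype={"site_id": str, "animal_id": str})
    _require_columns(trials, TRIAL_COLUMNS, "trial table")
    trials["correct"] = pd.array(trials["correct"], dtype="Int64")
    validate_trials(trials)
    trials = trials.sort_values(["site_id", "trial_index"], kind="stable").reset_index(drop=True)
    sites = load_sites(sites_path) if sites_path is not None else None
    return trials, sites


def write_trials(trials: pd.DataFrame, path) -> None:
    _require_columns(trials, TRIAL_COLUMNS, "trial table")
    trials.loc[:, TRIAL_COLUMNS].to_csv(path, sep="\t", index=False, na_rep="NA")


def load_sites(path) -> pd.DataFrame:
    sites = pd.read_csv(path, sep="\t", dtype={"site_id": str, "animal_id": str})
    _require_columns(sites, SITE_COLUMNS, "site table")
    return sites


def write_sites(sites: pd.DataFrame, path) -> None:
    _require_columns(sites, SITE_COLUMNS, "site table")
    sites.loc[:, SITE_COLUMNS].to_csv(path, sep="\t", index=False)


def site_meta_from_row(row) -> SiteMeta:
    levels = tuple(float(x) for x in str(row["disparity_levels"]).split(","))
    return SiteMeta(
        site_id=str(row["site_id"]),
        animal_id=str(row["animal_id"]),
        pref_direction=str(row["pref_direction"]),
        eccentricity_deg=float(row["eccentricity_deg"]),
        max_abs_disparity_deg=float(row["max_abs_disparity_deg"]),
        disparity_levels=levels,
    )


def site_meta_to_row(meta: SiteMeta) -> dict:
    return {
        "site_id": meta.site_id,
        "animal_id": meta.animal_id,
        "pref_direction": meta.pref_direction,
        "eccentricity_deg": meta.eccentricity_deg,
        "max_abs_disparity_deg": meta.max_abs_disparity_deg,
        "disparity_levels": ",".join(repr(float(d)) for d in meta.disparity_levels),
    }


def normalize_disparity(trials: pd.DataFrame, meta: SiteMeta | pd.DataFrame) -> pd.DataFrame:
    """Add the normalized-disparity column ``C = disparity_deg / site maximum``.

    Accepts a single :class:`SiteMeta` (single-site table) or a site table
    covering every site present.  C lies in [-1, 1]; a disparity exceeding the
    site's stated maximum means the metadata is inconsistent with the data.
    """
    out = trials.copy()
    if isinstance(meta, SiteMeta):
        max_by_site = {meta.site_id: meta.max_abs_disparity_deg}
    else:
        max_by_site = dict(zip(meta["site_id"].astype(str), meta["max_abs_disparity_deg"].astype(float)))
    missing = set(out["site_id"].astype(str)) - set(max_by_site)
    if missing:
        raise ValidationError(f"no site metadata for site(s): {sorted(missing)}")
    denom = out["site_id"].astype(str).map(max_by_site).to_numpy(dtype=float)
    if (denom <= 0).any():
        raise ValidationError("max_abs_disparity_deg must be > 0")
    d = out["disparity_deg"].to_numpy(dtype=float)
    if (np.abs(d) > denom * (1 + 1e-9)).any():
        raise ValidationError("disparity exceeds the site's stated maximum")
    out["C"] = d / denom
    return out


def inclusion_filter(trials: pd.DataFrame, min_trials: int = 10, min_levels: int = 5) -> pd.DataFrame:
    """Per-site inclusion: at least ``min_levels`` distinct disparity levels,
    each with >= ``min_trials`` microstimulated and >= ``min_trials``
    non-microstimulated trials.

    Returns a frame indexed by site_id with columns ``passed`` and ``reason``
    ('' when passed, 'levels' when too few distinct levels exist at all,
    'min trials' when levels exist but lack trials per condition).
    """
    records = []
    for site_id, sub in trials.groupby("site_id", sort=True):
        counts = (
            sub.groupby(["disparity_deg", "microstim"]).size().unstack("microstim", fill_value=0)
        )
        n_levels = counts.shape[0]
        stim = counts[1] if 1 in counts.columns else pd.Series(0, index=counts.index)
        nostim = counts[0] if 0 in counts.columns else pd.Series(0, index=counts.index)
        n_qualifying = int(((stim >= min_trials) & (nostim >= min_trials)).sum())
        if n_qualifying >= min_levels:
            passed, reason = True, ""
        elif n_levels < min_levels:
            passed, reason = False, "levels"
        else:
            passed, reason = False, "min trials"
        records.append(
            {
                "site_id": site_id,
                "passed": passed,
                "reason": reason,
                "n_levels": n_levels,
                "n_qualifying_levels": n_qualifying,
            }
        )
    if not records:
        return pd.DataFrame(
            columns=["site_id", "passed", "reason", "n_levels", "n_qualifying_levels"]
        ).set_index("site_id")
    return pd.DataFrame.from_records(records).set_index("site_id")
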