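"""Random-forest microbiota age and the microbiota-for-age Z score (MAZ).

A regression forest is trained on healthy samples to predict
chronological age from genus-level relative abundances ("microbiota
age").  Age-discriminatory genera are ranked by mean feature-importance
rank over repeated forest fits.  MAZ standardizes a sample's microbiota
age against the median and s.d. of microbiota age in healthy samples of
the same chronological-age stratum:

    MAZ = (microbiota age - median reference microbiota age)
          / (s.d. of reference microbiota age)
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from gutmaz.io_core import OtuTable, relative_abundance

__all__ = [
    "DEFAULT_AGE_STRATA",
    "AgeRegressorModel",
    "StratifiedAgeModel",
    "HealthyReference",
    "build_healthy_reference",
    "MazResult",
    "select_age_discriminatory_taxa",
    "train_age_model",
    "predict_microbiota_age",
    "compute_maz",
]

# age bands: <3, 3-9, 10-18, >18 (closed on the left, last open-ended)
DEFAULT_AGE_STRATA: tuple[tuple[float, float], ...] = (
    (0.0, 3.0),
    (3.0, 10.0),
    (10.0, 19.0),
    (19.0, np.inf),
)


def _stratum_index(
    age: float, strata: Sequence[tuple[float, float]]
) -> int:
    for k, (lo, hi) in enumerate(strata):
        if lo <= age < hi:
            return k
    raise ValueError(f"age {age} outside all strata {list(strata)}")


def _genus_matrix(
    table: OtuTable, genus_list: Sequence[str] | None = None
) -> tuple[np.ndarray, list[str]]:
    """Relative-abundance matrix aligned to ``genus_list`` (zeros if absent)."""
    rel = relative_abundance(table)
    if genus_list is None:
        return rel, list(table.otu_ids)
    idx = {g: j for j, g in enumerate(table.otu_ids)}
    out = np.zeros((table.n_samples, len(genus_list)))
    missing = []
    for k, g in enumerate(genus_list):
        j = idx.get(g)
        if j is None:
            missing.append(g)
        else:
            out[:, k] = rel[:, j]
    if missing:
        warnings.warn(
            f"{len(missing)} model genera absent from table, imputed as 0: "
            f"{missing[:5]}"
        )
    return out, list(genus_list)


@dataclass
class AgeRegressorModel:
    """One trained regression forest with its feature list and age range."""

    genus_list: list[str]
    forest: RandomForestRegressor
    age_range: tuple[float, float]
    oob_r2: float

    def predict(self, genus_table: OtuTable) -> np.ndarray:
        x, _ = _genus_matrix(genus_table, self.genus_list)
        if not x.any(axis=1).all():
            warnings.warn("all-zero abundance rows predicted at forest mean response")
        return self.forest.predict(x)


@dataclass
class StratifiedAgeModel:
    """One forest per chronological-age stratum."""

    strata: tuple[tuple[float, float], ...]
    models: list[AgeRegressorModel]

    def model_for_age(self, age: float) -> AgeRegressorModel:
        return self.models[_stratum_index(age, self.strata)]


@dataclass
class HealthyReference:
    """Per-stratum (median, s.d.) of microbiota age in healthy samples."""

    strata: tuple[tuple[float, float], ...]
    medians: np.ndarray
    sds: np.ndarray
    n_per_stratum: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        if (np.asarray(self.sds) <= 0).any():
            bad = np.flatnonzero(np.asarray(self.sds) <= 0)
            raise ValueError(
                f"non-positive reference s.d. in strata {bad.tolist()}"
            )

    @classmethod
    def from_predictions(
        cls,
        microbiota_ages: Sequence[float],
        chronological_ages: Sequence[float],
        strata: Sequence[tuple[float, float]] = DEFAULT_AGE_STRATA,
    ) -> "HealthyReference":
        ma = np.asarray(microbiota_ages, dtype=float)
        ca = np.asarray(chronological_ages, dtype=float)
        strata = tuple(tuple(s) for s in strata)
        idx = np.array([_stratum_index(a, strata) for a in ca])
        medians = np.empty(len(strata))
        sds = np.empty(len(strata))
        counts = np.zeros(len(strata), dtype=int)
        for k in range(len(strata)):
            vals = ma[idx == k]
            if len(vals) < 2:
                raise ValueError(
                    f"stratum {strata[k]} has {len(vals)} reference samples "
                    "(need >= 2)"
                )
            medians[k] = np.median(vals)
            sds[k] = vals.std(ddof=1)
            counts[k] = len(vals)
        return cls(strata, medians, sds, counts)


def build_healthy_reference(
    model: "AgeRegressorModel",
    genus_table: OtuTable,
    ages: Sequence[float],
    strata: Sequence[tuple[float, float]] = DEFAULT_AGE_STRATA,
    use_oob: bool = True,
) -> HealthyReference:
    """Reference (median, s.d.) strata from healthy training samples.

    With ``use_oob`` the forest's out-of-bag predictions are used, which
    behave like held-out predictions and avoid the overfit compression
    of in-sample scores.
    """
    ages = np.asarray(ages, dtype=float)
    if use_oob and hasattr(model.forest, "oob_prediction_"):
        if len(model.forest.oob_prediction_) != len(ages):
            raise ValueError("ages must match the model's training samples")
        preds = model.forest.oob_prediction_
    else:
        preds = model.predict(genus_table)
    return HealthyReference.from_predictions(preds, ages, strata)


@dataclass
class MazResult:
    sample_id: str
    chronological_age: float
    microbiota_age: float
    maz: float


def select_age_discriminatory_taxa(
    genus_table: OtuTable,
    ages: Sequence[float],
    k: int = 30,
    n_iter: int = 100,
    n_trees: int = 500,
    seed: int = 0,
) -> list[str]:
    """Rank genera by mean feature-importance rank over repeated forests.

    Trains ``n_iter`` regression forests with different seeds and
    returns the top-``k`` genera with the best (lowest) mean rank of
    impurity-based feature importance.
    """
    ages = np.asarray(ages, dtype=float)
    if genus_table.n_otus < 2:
        raise ValueError("need at least 2 genera")
    if k > genus_table.n_otus:
        raise ValueError(
            f"k={k} exceeds the number of genera ({genus_table.n_otus})"
        )
    if np.ptp(ages) == 0:
        raise ValueError("ages must vary")
    x = relative_abundance(genus_table)
    rank_sum = np.zeros(genus_table.n_otus)
    for it in range(n_iter):
        forest = RandomForestRegressor(
            n_estimators=n_trees,
            max_features=1.0 / 3.0,
            random_state=seed + it,
            n_jobs=1,
        )
        forest.fit(x, ages)
        # rank 0 = most important
        order = np.argsort(-forest.feature_importances_, kind="stable")
        ranks = np.empty_like(order)
        ranks[order] = np.arange(len(order))
        rank_sum += ranks
    best = np.argsort(rank_sum, kind="stable")[:k]
    return [genus_table.otu_ids[j] for j in best]


def _fit_forest(
    x: np.ndarray, y: np.ndarray, n_trees: int, seed: int
) -> tuple[RandomForestRegressor, float]:
    forest = RandomForestRegressor(
        n_estimators=n_trees,
        max_features=1.0 / 3.0,  # mirrors R randomForest's regression default mtry=p/3
        oob_score=True,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # few-sample OOB warnings
        forest.fit(x, y)
    return forest, float(forest.oob_score_)


def train_age_model(
    genus_table: OtuTable,
    ages: Sequence[float],
    genus_list: Sequence[str] | None = None,
    stratify: bool = False,
    strata: Sequence[tuple[float, float]] = DEFAULT_AGE_STRATA,
    n_trees: int = 500,
    min_per_stratum: int = 20,
    seed: int = 0,
) -> AgeRegressorModel | StratifiedAgeModel:
    """Train the microbiota-age regression forest(s).

    With ``stratify`` one forest is trained per age stratum (default
    bands <3, 3-10, 10-19, >=19 years); otherwise a single forest on the
    full age range.  The out-of-bag R^2 is recorded on each model.
    """
    ages = np.asarray(ages, dtype=float)
    if np.ptp(ages) == 0:
        raise ValueError("ages must vary")
    x, genus_list_used = _genus_matrix(genus_table, genus_list)
    if not stratify:
        if len(ages) < min_per_stratum:
            raise ValueError(
                f"need >= {min_per_stratum} training samples, got {len(ages)}"
            )
        forest, oob = _fit_forest(x, ages, n_trees, seed)
        return AgeRegressorModel(
            genus_list_used, forest, (float(ages.min()), float(ages.max())), oob
        )
    strata = tuple(tuple(s) for s in strata)
    models = []
    for k, (lo, hi) in enumerate(strata):
        mask = (ages >= lo) & (ages < hi)
        if mask.sum() < min_per_stratum:
            raise ValueError(
                f"stratum [{lo}, {hi}) has {int(mask.sum())} samples "
                f"(need >= {min_per_stratum})"
            )
        forest, oob = _fit_forest(x[mask], ages[mask], n_trees, seed + k)
        models.append(
            AgeRegressorModel(genus_list_used, forest, (float(lo), float(hi)), oob)
        )
    return StratifiedAgeModel(strata, models)


def predict_microbiota_age(
    model: AgeRegressorModel | StratifiedAgeModel,
    genus_table: OtuTable,
    ages: Sequence[float] | None = None,
) -> np.ndarray:
    """Predict microbiota age for each sample.

    With a stratified model, each sample is scored by the forest of its
    chronological-age stratum (``ages`` required).
    """
    if isinstance(model, StratifiedAgeModel):
        if ages is None:
            raise ValueError("chronological ages required for stratified models")
        ages = np.asarray(ages, dtype=float)
        out = np.empty(genus_table.n_samples)
        strata_idx = np.array(
            [_stratum_index(a, model.strata) for a in ages]
        )
        for k in np.unique(strata_idx):
            mask = strata_idx == k
            sub = genus_table.select_samples(
                [s for s, m in zip(genus_table.sample_ids, mask) if m]
            )
            out[mask] = model.models[k].predict(sub)
        return out
    return model.predict(genus_table)


def compute_maz(
    microbiota_ages: Sequence[float],
    chronological_ages: Sequence[float],
    reference: HealthyReference,
    sample_ids: Sequence[str] | None = None,
) -> list[MazResult]:
    """MAZ per sample against the healthy same-age reference stratum."""
    ma = np.asarray(microbiota_ages, dtype=float)
    ca = np.asarray(chronological_ages, dtype=float)
    if len(ma) != len(ca):
        raise ValueError("microbiota and chronological age lengths differ")
    if sample_ids is None:
        sample_ids = [f"S{i}" for i in range(len(ma))]
    out = []
    for sid, m, c in zip(sample_ids, ma, ca):
        k = _stratum_index(c, reference.strata)
        maz = (m - reference.medians[k]) / reference.sds[k]
        out.append(MazResult(str(sid), float(c), float(m), float(maz)))
    return out


def maz_to_frame(results: Sequence[MazResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "chronological_age": r.chronological_age,
                "microbiota_age": r.microbiota_age,
                "maz": r.maz,
            }
            for r in results
        ]
    ).set_index("sample_id")


def save_reference(reference: HealthyReference, path: str | Path) -> None:
    data = {
        "strata": [[lo, None if np.isinf(hi) else hi] for lo, hi in reference.strata],
        "medians": np.asarray(reference.medians).tolist(),
        "sds": np.asarray(reference.sds).tolist(),
        "n_per_stratum": np.asarray(reference.n_per_stratum).tolist(),
    }
    Path(path).write_text(json.dumps(data, indent=2) + "\n")


def load_reference(path: str | Path) -> HealthyReference:
    data = json.loads(Path(path).read_text())
    strata = tuple(
        (float(lo), np.inf if hi is None else float(hi))
        for lo, hi in data["strata"]
    )
    return HealthyReference(
        strata,
        np.asarray(data["medians"], dtype=float),
        np.asarray(data["sds"], dtype=float),
        np.asarray(data["n_per_stratum"], dtype=int),
    )
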