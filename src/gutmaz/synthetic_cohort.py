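"""Synthetic age-structured cohort generator with known ground truth.

Genus mean abundances follow logistic-in-age trajectories; each genus
belongs to one of five classes:

- ``age_discriminatory``: abundance rises (or falls) with age in everyone;
- ``stunted_colonization``: normal maturation ramp whose midpoint is
  delayed in disease;
- ``disrupted_colonization``: non-monotone (bump-shaped) trajectory,
  flattened or shifted in disease via the disease multiplier;
- ``persistent_overgrowth``: flat in health, elevated at all ages in
  disease;
- ``background``: flat, unaffected by age or disease.

Counts are drawn Dirichlet-multinomial per sample at a drawn depth, and
genus mass is split across member OTUs by a fixed geometric series so
both OTU- and genus-level stages see structure.  A treatment -> mediator
-> outcome structure with known standardized path coefficients is layered
on top for the mediation stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from gutmaz.io_core import (
    OtuTable,
    SampleMetadata,
    TaxonomyMap,
    write_metadata,
    write_otu_table,
    write_taxonomy,
)

__all__ = [
    "TrajectorySpec",
    "CohortSpec",
    "GeneratedCohort",
    "default_genus_panel",
    "simulate_counts",
    "simulate_mediation_outcomes",
    "generate_cohort",
]

TRAJECTORY_CLASSES = (
    "age_discriminatory",
    "stunted_colonization",
    "disrupted_colonization",
    "persistent_overgrowth",
    "background",
)


@dataclass
class TrajectorySpec:
    """Mean log-abundance trajectory of one genus."""

    genus: str
    traj_class: str
    baseline: float = 0.0
    midpoint: float = 2.0
    slope: float = 1.0
    amplitude: float = 2.0
    disease_multiplier: float = 1.0
    disease_midpoint_shift: float = 0.0

    def __post_init__(self) -> None:
        if self.traj_class not in TRAJECTORY_CLASSES:
            raise ValueError(
                f"unknown trajectory class {self.traj_class!r}; "
                f"expected one of {TRAJECTORY_CLASSES}"
            )
        if not np.isfinite(self.slope):
            raise ValueError("slope must be finite")
        if self.disease_multiplier <= 0:
            raise ValueError("disease_multiplier must be > 0")

    def log_mean(self, age: np.ndarray, diseased: np.ndarray) -> np.ndarray:
        """Unnormalized log mean abundance at given ages/disease states."""
        age = np.asarray(age, dtype=float)
        diseased = np.asarray(diseased, dtype=bool)
        cls = self.traj_class
        if cls == "background":
            m = np.full_like(age, self.baseline)
        elif cls in ("age_discriminatory", "stunted_colonization"):
            mid = np.where(
                diseased, self.midpoint + self.disease_midpoint_shift, self.midpoint
            )
            m = self.baseline + self.amplitude / (
                1.0 + np.exp(-self.slope * (age - mid))
            )
        elif cls == "disrupted_colonization":
            # bump: product of a rising and a falling logistic
            rise = 1.0 / (1.0 + np.exp(-self.slope * (age - self.midpoint)))
            fall = 1.0 / (1.0 + np.exp(self.slope * (age - self.midpoint - 4.0)))
            m = self.baseline + self.amplitude * rise * fall
        elif cls == "persistent_overgrowth":
            m = np.full_like(age, self.baseline)
        else:  # pragma: no cover
            raise AssertionError(cls)
        if cls != "age_discriminatory":
            m = m + np.where(diseased, np.log(self.disease_multiplier), 0.0)
        return m


def default_genus_panel(
    n_background: int = 20,
    n_age: int = 8,
    n_stunted: int = 4,
    n_disrupted: int = 2,
    n_overgrowth: int = 2,
    age_range: tuple[float, float] = (0.0, 20.0),
    disease_midpoint_shift: float = 6.0,
    overgrowth_multiplier: float = 4.0,
    rng: np.random.Generator | None = None,
) -> list[TrajectorySpec]:
    """A reasonable default panel spanning all five trajectory classes."""
    rng = rng or np.random.default_rng(0)
    lo, hi = age_range
    panel: list[TrajectorySpec] = []
    for i in range(n_age):
        panel.append(
            TrajectorySpec(
                genus=f"AgeGenus{i + 1}",
                traj_class="age_discriminatory",
                baseline=float(rng.uniform(-1.0, 0.5)),
                midpoint=float(lo + (hi - lo) * (i + 1) / (n_age + 1)),
                slope=float(rng.uniform(0.6, 1.2)) * (1 if i % 2 == 0 else -1),
                amplitude=float(rng.uniform(2.0, 3.0)),
            )
        )
    for i in range(n_stunted):
        panel.append(
            TrajectorySpec(
                genus=f"StuntedGenus{i + 1}",
                traj_class="stunted_colonization",
                baseline=float(rng.uniform(-1.0, 0.0)),
                midpoint=float(lo + (hi - lo) * (i + 1) / (n_stunted + 2)),
                slope=float(rng.uniform(0.8, 1.5)),
                amplitude=float(rng.uniform(2.0, 3.0)),
                disease_midpoint_shift=disease_midpoint_shift,
            )
        )
    for i in range(n_disrupted):
        panel.append(
            TrajectorySpec(
                genus=f"DisruptedGenus{i + 1}",
                traj_class="disrupted_colonization",
                baseline=float(rng.uniform(-1.0, 0.0)),
                midpoint=float(rng.uniform(lo + 1, (lo + hi) / 2)),
                slope=float(rng.uniform(0.8, 1.5)),
                amplitude=float(rng.uniform(2.0, 3.0)),
                disease_multiplier=0.5,
            )
        )
    for i in range(n_overgrowth):
        panel.append(
            TrajectorySpec(
                genus=f"OvergrowthGenus{i + 1}",
                traj_class="persistent_overgrowth",
                baseline=float(rng.uniform(-0.5, 0.5)),
                disease_multiplier=overgrowth_multiplier,
            )
        )
    for i in range(n_background):
        panel.append(
            TrajectorySpec(
                genus=f"BgGenus{i + 1}",
                traj_class="background",
                baseline=float(rng.uniform(-1.5, 1.0)),
            )
        )
    return panel


@dataclass
class CohortSpec:
    """Full specification of a synthetic cohort."""

    n_samples: int = 200
    age_range: tuple[float, float] = (0.0, 20.0)
    disease_prevalence: float = 0.5
    genus_panel: list[TrajectorySpec] = field(default_factory=default_genus_panel)
    otus_per_genus: int = 10
    otu_split_ratio: float = 0.5
    dirichlet_concentration: float = 200.0
    depth_mean: int = 20000
    depth_spread: float = 0.25
    mediation_a: float = 0.5
    mediation_b: float = 0.4
    mediation_c_prime: float = 0.2
    covariate_effect: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if not 0 < self.disease_prevalence < 1:
            raise ValueError("disease_prevalence must be in (0, 1)")
        if self.depth_mean < 100:
            raise ValueError("depth_mean must be >= 100")
        if self.otus_per_genus < 1:
            raise ValueError("otus_per_genus must be >= 1")

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["genus_panel"] = [asdict(t) for t in self.genus_panel]
        Path(path).write_text(json.dumps(d, indent=2) + "\n")

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        d = dict(d)
        if "genus_panel" in d:
            d["genus_panel"] = [
                t if isinstance(t, TrajectorySpec) else TrajectorySpec(**t)
                for t in d["genus_panel"]
            ]
        if "age_range" in d:
            d["age_range"] = tuple(d["age_range"])
        return cls(**d)


@dataclass
class GeneratedCohort:
    """A simulated cohort with aligned ground truth."""

    table: OtuTable
    taxonomy: TaxonomyMap
    metadata: SampleMetadata
    ground_truth: dict

    @property
    def genus_names(self) -> list[str]:
        return list(self.ground_truth["genus_names"])


def _trajectory_relative_abundance(
    panel: Sequence[TrajectorySpec], ages: np.ndarray, diseased: np.ndarray
) -> np.ndarray:
    """Expected genus relative abundances (softmax of log means)."""
    logm = np.stack([t.log_mean(ages, diseased) for t in panel], axis=1)
    logm -= logm.max(axis=1, keepdims=True)
    w = np.exp(logm)
    return w / w.sum(axis=1, keepdims=True)


def simulate_counts(spec: CohortSpec, seed: int | None = None) -> GeneratedCohort:
    """Draw an OTU count table from the cohort spec.

    Each sample: ages uniform on the spec range, disease Bernoulli at
    the spec prevalence, genus proportions Dirichlet around the
    trajectory mean, OTU proportions a fixed geometric split within each
    genus, counts a single multinomial at the drawn depth (so row sums
    equal the drawn depth exactly).
    """
    if not spec.genus_panel:
        raise ValueError("genus panel is empty")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.n_samples
    lo, hi = spec.age_range
    ages = rng.uniform(lo, hi, size=n)
    diseased = rng.random(n) < spec.disease_prevalence

    p_genus = _trajectory_relative_abundance(spec.genus_panel, ages, diseased)
    # Dirichlet draw per sample for compositional overdispersion
    alpha = spec.dirichlet_concentration * p_genus
    theta = np.empty_like(p_genus)
    for i in range(n):
        theta[i] = rng.dirichlet(np.maximum(alpha[i], 1e-8))

    # split genus mass over member OTUs by a geometric series
    k = spec.otus_per_genus
    r = spec.otu_split_ratio
    split = r ** np.arange(k)
    split = split / split.sum()
    otu_theta = (theta[:, :, None] * split[None, None, :]).reshape(n, -1)

    depths = np.maximum(
        100,
        rng.normal(spec.depth_mean, spec.depth_spread * spec.depth_mean, n).astype(
            np.int64
        ),
    )
    counts = np.empty_like(otu_theta, dtype=np.int64)
    for i in range(n):
        counts[i] = rng.multinomial(depths[i], otu_theta[i])

    genus_names = [t.genus for t in spec.genus_panel]
    otu_ids = [f"{g}_otu{j + 1}" for g in genus_names for j in range(k)]
    sample_ids = [f"S{i + 1:05d}" for i in range(n)]
    table = OtuTable(sample_ids, otu_ids, counts)
    taxonomy = TaxonomyMap(
        {
            f"{g}_otu{j + 1}": {"kingdom": "Bacteria", "genus": g}
            for g in genus_names
            for j in range(k)
        }
    )

    sex = rng.integers(0, 2, n)
    bmi = np.clip(rng.normal(18.0, 3.0, n) + 0.3 * ages, 10, 45)
    district = rng.integers(1, 5, n)
    uccs = (diseased & (rng.random(n) < 0.7)).astype(int)
    meta = pd.DataFrame(
        {
            "age": ages,
            "group": np.where(diseased, "disease", "control"),
            "sex": sex,
            "bmi": bmi,
            "district": district,
            "uccs": uccs,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    ground_truth = {
        "genus_names": genus_names,
        "trajectory_classes": {t.genus: t.traj_class for t in spec.genus_panel},
        "true_genus_relative_abundance": p_genus,
        "depths": depths,
        "diseased": diseased.astype(int),
        "ages": ages,
    }
    return GeneratedCohort(
        table,
        taxonomy,
        SampleMetadata(meta, allowed_groups=("control", "disease")),
        ground_truth,
    )


def simulate_mediation_outcomes(
    cohort: GeneratedCohort,
    a: float,
    b: float,
    c_prime: float,
    seed: int = 0,
    covariate_effect: float = 0.1,
    outcome_link: str = "logistic",
    outcome_intercept: float = -1.0,
) -> SampleMetadata:
    """Attach a mediator and a binary comorbidity outcome to the cohort.

    The mediator is ``M = a * T_std + covariate terms + noise`` with unit
    marginal variance; the outcome is Bernoulli with a logistic (default)
    or linear-probability link on ``b*M + c_prime*T_std + covariates``.
    The true indirect effect ``a*b`` is recorded in the ground truth.
    """
    for name, v in (("a", a), ("b", b)):
        if abs(v) > 5:
            raise ValueError(f"|{name}| > 5 is implausibly large")
    rng = np.random.default_rng(seed)
    df = cohort.metadata.frame.copy()
    n = len(df)
    t = (df["group"] == "disease").astype(float).to_numpy()
    t_std = (t - t.mean()) / t.std() if t.std() > 0 else t

    def z(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        s = x.std()
        return (x - x.mean()) / s if s > 0 else x - x.mean()

    cov = covariate_effect * (
        z(df["age"]) + z(df["bmi"]) + z(df["sex"]) + z(df["uccs"]) + z(df["district"])
    )
    resid_var = 1.0 - min(a**2 + np.var(cov), 0.99)
    m = a * t_std + cov + rng.normal(0.0, np.sqrt(resid_var), n)

    eta = outcome_intercept + b * m + c_prime * t_std + cov
    if outcome_link == "logistic":
        p = 1.0 / (1.0 + np.exp(-eta))
    elif outcome_link == "linear":
        p = np.clip(0.5 + 0.25 * (eta - outcome_intercept), 0.0, 1.0)
    else:
        raise ValueError(f"unknown outcome_link {outcome_link!r}")
    y = (rng.random(n) < p).astype(int)

    df["mediator_true"] = m
    df["comorbidity"] = y
    cohort.ground_truth["mediation"] = {
        "a": a,
        "b": b,
        "c_prime": c_prime,
        "indirect": a * b,
        "outcome_link": outcome_link,
        "true_mediator": m,
    }
    meta = SampleMetadata(df, allowed_groups=("control", "disease"))
    cohort.metadata = meta
    return meta


def generate_cohort(
    spec: CohortSpec, out_dir: str | Path | None = None, seed: int | None = None
) -> GeneratedCohort:
    """Compose count and mediation simulators; optionally write artifacts.

    Writes OTU TSV, taxonomy TSV, metadata CSV and ground-truth JSON
    into ``out_dir`` when given.
    """
    cohort = simulate_counts(spec, seed=seed)
    base_seed = spec.seed if seed is None else seed
    simulate_mediation_outcomes(
        cohort,
        spec.mediation_a,
        spec.mediation_b,
        spec.mediation_c_prime,
        seed=base_seed + 1,
        covariate_effect=spec.covariate_effect,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        try:
            write_otu_table(cohort.table, out / "otu_table.tsv")
            write_taxonomy(cohort.taxonomy, out / "taxonomy.tsv")
            write_metadata(cohort.metadata, out / "metadata.csv")
            gt = {
                k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in cohort.ground_truth.items()
                if k != "mediation"
            }
            med = cohort.ground_truth.get("mediation")
            if med is not None:
                gt["mediation"] = {
                    k: (v.tolist() if isinstance(v, np.ndarray) else v)
                    for k, v in med.items()
                }
            (out / "ground_truth.json").write_text(json.dumps(gt) + "\n")
        except OSError as e:
            raise OSError(f"failed writing cohort artifacts to {out}: {e}") from e
    return cohort
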