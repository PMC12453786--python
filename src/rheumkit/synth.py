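"""Synthetic rheumatic/autoimmune cohort generator.

Generates patient tables with the statistical structure the downstream
benchmark assumes: 14 typed clinical features (9 numeric lab/demographic
measurements, 5 binary serology markers plus Gender), a 7-value diagnosis
label (RA, ReA, AS, SS, SLE, PA, N), configurable per-class sample counts,
and MCAR per-column missingness injected after generation.

Numeric features are drawn from a *moment-matched* truncated normal: the
latent location is solved per (feature, class) so that the mean *after*
truncation to [lo, hi] equals the configured target.  Naive truncation
would bias bounded features with near-boundary means (the age marginal,
for instance, would drift upward by several years) and break marginal
recovery.  Class-conditional numeric shift profiles are re-centered to a
zero cohort-weighted mean so that class structure is added without moving
the configured marginal means.  Binary features are Bernoulli with a
per-class positivity probability falling back to the marginal one.

The class-conditional shift profiles shipped in the default configuration
are invented (marginal statistics say nothing about per-class structure);
they encode textbook serology: see ``data/default_cohort.yaml``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import optimize
from scipy.stats import truncnorm

__all__ = [
    "CLASSES",
    "LABEL_COL",
    "FeatureSpec",
    "ClassProfile",
    "GeneratorConfig",
    "load_config",
    "default_config",
    "generate_cohort",
    "inject_missingness",
    "summarize",
]

#: Canonical diagnosis vocabulary.
CLASSES: tuple[str, ...] = ("RA", "ReA", "AS", "SS", "SLE", "PA", "N")

LABEL_COL = "Class"


class ConfigurationError(ValueError):
    """Raised when a generator configuration violates its invariants."""


@dataclass(frozen=True)
class FeatureSpec:
    """Marginal description of one clinical feature.

    Numeric features carry an admissible range [lo, hi] (measurement
    units are the clinical ones: ESR in mm/hr, CRP/C3/C4 in mg/dL, RF and
    anti-CCP in IU/mL, age in years) plus target mean/sd; binary features
    carry a positivity probability instead.
    """

    name: str
    kind: str  # "numeric" | "binary"
    lo: float | None = None
    hi: float | None = None
    mean: float | None = None
    sd: float | None = None
    p_positive: float | None = None
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("numeric", "binary"):
            raise ConfigurationError(f"feature {self.name!r}: kind must be numeric or binary")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigurationError(
                f"feature {self.name!r}: missing_rate must lie in [0, 1), got {self.missing_rate}"
            )
        if self.kind == "numeric":
            if self.lo is None or self.hi is None or self.mean is None or self.sd is None:
                raise ConfigurationError(f"feature {self.name!r}: numeric needs lo/hi/mean/sd")
            if not self.lo < self.hi:
                raise ConfigurationError(f"feature {self.name!r}: requires lo < hi")
            if self.sd <= 0:
                raise ConfigurationError(f"feature {self.name!r}: sd must be > 0")
        else:
            if self.lo is not None or self.hi is not None:
                raise ConfigurationError(f"feature {self.name!r}: binary takes no lo/hi")
            if self.p_positive is None or not (0.0 <= self.p_positive <= 1.0):
                raise ConfigurationError(f"feature {self.name!r}: binary needs p_positive in [0, 1]")


@dataclass(frozen=True)
class ClassProfile:
    """Sample count and per-feature shifts of one diagnosis class.

    ``shifts`` maps feature name to a mean offset (numeric features) or an
    overriding positivity probability (binary features).
    """

    label: str
    n: int
    shifts: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ConfigurationError(f"class {self.label!r}: n must be > 0, got {self.n}")


@dataclass(frozen=True)
class GeneratorConfig:
    feature_specs: tuple[FeatureSpec, ...]
    class_profiles: tuple[ClassProfile, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        names = [f.name for f in self.feature_specs]
        if len(names) != len(set(names)):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ConfigurationError(f"duplicate feature spec(s): {dup}")
        if not self.feature_specs or not self.class_profiles:
            raise ConfigurationError("need at least one feature spec and one class profile")
        labels = [p.label for p in self.class_profiles]
        if len(labels) != len(set(labels)):
            raise ConfigurationError("duplicate class labels in profiles")
        by_name = {f.name: f for f in self.feature_specs}
        for prof in self.class_profiles:
            for feat, value in prof.shifts.items():
                if feat not in by_name:
                    raise ConfigurationError(
                        f"class {prof.label!r}: shift refers to unknown feature {feat!r}"
                    )
                if by_name[feat].kind == "binary" and not (0.0 <= value <= 1.0):
                    raise ConfigurationError(
                        f"class {prof.label!r}: positivity for {feat!r} must lie in [0, 1]"
                    )

    @property
    def n_total(self) -> int:
        return sum(p.n for p in self.class_profiles)

    def spec(self, name: str) -> FeatureSpec:
        for f in self.feature_specs:
            if f.name == name:
                return f
        raise KeyError(name)


def load_config(path: str | Path) -> GeneratorConfig:
    """Read a generator configuration from YAML (or JSON, a YAML subset)."""
    raw = yaml.safe_load(Path(path).read_text())
    try:
        feats = tuple(FeatureSpec(**f) for f in raw["features"])
        profs = tuple(
            ClassProfile(c["label"], int(c["n"]), dict(c.get("shifts", {}))) for c in raw["classes"]
        )
    except (KeyError, TypeError) as exc:
        raise ConfigurationError(f"malformed generator config {path}: {exc}") from exc
    return GeneratorConfig(feats, profs, seed=int(raw.get("seed", 0)))


def default_config(seed: int | None = None) -> GeneratorConfig:
    """The shipped default cohort: published marginals and class sizes."""
    cfg = load_config(Path(__file__).parent / "data" / "default_cohort.yaml")
    if seed is not None:
        cfg = GeneratorConfig(cfg.feature_specs, cfg.class_profiles, seed=seed)
    return cfg


def _matched_loc(target_mean: float, sd: float, lo: float, hi: float) -> float:
    """Latent normal location whose [lo, hi]-truncated mean equals target_mean."""
    span = hi - lo
    # Keep the target strictly inside the support; the truncated mean can
    # never reach the bounds themselves.
    target = min(max(target_mean, lo + 1e-9 * span), hi - 1e-9 * span)

    def gap(loc: float) -> float:
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return truncnorm.mean(a, b, loc=loc, scale=sd) - target

    return optimize.brentq(gap, lo - 12 * sd, hi + 12 * sd, xtol=1e-10)


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Generate a complete (no missing values) patient table.

    Deterministic given ``config.seed``; rows are grouped by class in
    profile order, per-class counts equal each profile's ``n``.
    """
    rng = np.random.default_rng(config.seed)
    weights = np.array([p.n for p in config.class_profiles], dtype=float)
    weights /= weights.sum()

    # Re-center each numeric feature's shift profile so the cohort-level
    # mean stays at the configured marginal value.
    centered: dict[str, dict[str, float]] = {}
    for spec in config.feature_specs:
        if spec.kind != "numeric":
            continue
        shifts = np.array([p.shifts.get(spec.name, 0.0) for p in config.class_profiles])
        shifts = shifts - float(weights @ shifts)
        centered[spec.name] = {
            p.label: s for p, s in zip(config.class_profiles, shifts)
        }

    blocks = []
    for prof in config.class_profiles:
        cols: dict[str, np.ndarray] = {}
        for spec in config.feature_specs:
            if spec.kind == "numeric":
                target = spec.mean + centered[spec.name][prof.label]
                loc = _matched_loc(target, spec.sd, spec.lo, spec.hi)
                a, b = (spec.lo - loc) / spec.sd, (spec.hi - loc) / spec.sd
                cols[spec.name] = truncnorm.rvs(
                    a, b, loc=loc, scale=spec.sd, size=prof.n, random_state=rng
                )
            else:
                p = prof.shifts.get(spec.name, spec.p_positive)
                cols[spec.name] = (rng.random(prof.n) < p).astype(float)
        block = pd.DataFrame(cols)
        block[LABEL_COL] = prof.label
        blocks.append(block)
    return pd.concat(blocks, ignore_index=True)


def inject_missingness(table: pd.DataFrame, specs: Sequence[FeatureSpec], seed: int) -> pd.DataFrame:
    """MCAR-mask each feature column at its spec's ``missing_rate``.

    The label column is never masked.  Columns targeted by a nonzero rate
    must not already contain missing values.
    """
    out = table.copy()
    rng = np.random.default_rng(seed)
    for spec in specs:
        if spec.name not in out.columns:
            raise KeyError(f"feature {spec.name!r} not in table")
        if spec.missing_rate == 0.0:
            continue
        if out[spec.name].isna().any():
            raise ValueError(f"column {spec.name!r} already contains missing values")
        mask = rng.random(len(out)) < spec.missing_rate
        col = out[spec.name].astype(float)
        col[mask] = np.nan
        out[spec.name] = col
    return out


def summarize(table: pd.DataFrame, label_col: str = LABEL_COL) -> pd.DataFrame:
    """Per-feature descriptive table: count, missing %, min/max, mean/std.

    A single observed value yields std 0 (flagged in the ``degenerate``
    column rather than NaN).
    """
    if table.empty:
        raise ValueError("cannot summarize an empty table")
    rows = {}
    for col in table.columns:
        if col == label_col:
            continue
        s = table[col]
        observed = s.dropna()
        degenerate = len(observed) < 2
        rows[col] = {
            "count": int(observed.size),
            "missing": int(s.isna().sum()),
            "missing_pct": 100.0 * s.isna().mean(),
            "min": float(observed.min()) if observed.size else np.nan,
            "max": float(observed.max()) if observed.size else np.nan,
            "mean": float(observed.mean()) if observed.size else np.nan,
            "std": 0.0 if degenerate else float(observed.std(ddof=1)),
            "degenerate": degenerate,
        }
    return pd.DataFrame(rows).T
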