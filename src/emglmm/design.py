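"""Stacked fixed-effects design with muscle-specific coefficient blocks.

Every covariate gets four coefficients, one per muscle (muscle-major,
covariate-minor column order).  Three term groups exist:

* main effects — active on every observation;
* affected-side interactions — (scaled covariate) x affected indicator;
* affected-only terms — covariates that are only meaningful on the affected
  arm (exercise / physiotherapy), entered as covariate x affected indicator.

Covariates conventionally reported "x 100" (elevation, age, duration, SPADI
pain and disability) are divided by 100 before entering the design, so the
fitted coefficients land on the customary reporting scale.  Scaling is
applied before interactions are formed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import MUSCLES, ObservationTable, SeriesLayout
from .errors import SpecError

DEFAULT_MAIN_EFFECTS = (
    "intercept",
    "elevation",
    "move_up",
    "affected",
    "hand_left",
    "dominant",
    "age",
    "duration",
    "spadi_pain",
    "spadi_disability",
    "wle",
    "chemo",
)
DEFAULT_AFFECTED_INTERACTIONS = ("elevation", "dominant", "duration", "spadi_pain")
DEFAULT_AFFECTED_ONLY = ("exercise_6m", "exercise_now", "physio_now", "physio_ever")
DEFAULT_SCALE_FACTORS = {
    "elevation": 0.01,
    "age": 0.01,
    "duration": 0.01,
    "spadi_pain": 0.01,
    "spadi_disability": 0.01,
}

# design term -> observation-table column (series-level terms handled specially)
_TERM_SOURCES = {
    "age": "age_years",
    "duration": "duration_days",
    "spadi_pain": "spadi_pain_mm",
    "spadi_disability": "spadi_disability_mm",
    "hand_left": "hand_left",
    "wle": "wle",
    "chemo": "chemo",
    "exercise_6m": "exercise_6m",
    "exercise_now": "exercise_now",
    "physio_now": "physio_now",
    "physio_ever": "physio_ever",
}

TERM_GROUPS = ("affected_interactions", "affected_only")


@dataclass(frozen=True)
class DesignSpec:
    """Which covariates enter which of the three term groups, plus scaling."""

    main_effects: tuple = DEFAULT_MAIN_EFFECTS
    affected_interactions: tuple = DEFAULT_AFFECTED_INTERACTIONS
    affected_only: tuple = DEFAULT_AFFECTED_ONLY
    scale_factors: dict = field(default_factory=lambda: dict(DEFAULT_SCALE_FACTORS))

    def __post_init__(self):
        object.__setattr__(self, "main_effects", tuple(self.main_effects))
        object.__setattr__(self, "affected_interactions", tuple(self.affected_interactions))
        object.__setattr__(self, "affected_only", tuple(self.affected_only))
        inter = set(self.affected_interactions) & set(self.affected_only)
        if inter:
            raise SpecError(f"terms in more than one group: {sorted(inter)}")
        for name in self.affected_interactions:
            if name not in self.main_effects:
                raise SpecError(f"interaction term {name!r} lacks a main effect")

    @property
    def p_per_muscle(self) -> int:
        return len(self.main_effects) + len(self.affected_interactions) + len(self.affected_only)

    @property
    def terms(self) -> tuple:
        """Flat (group-tagged) term labels in column order within one muscle block."""
        return (
            tuple(self.main_effects)
            + tuple(f"{t}:affected" for t in self.affected_interactions)
            + tuple(f"{t}@affected" for t in self.affected_only)
        )

    def to_dict(self) -> dict:
        return {
            "main_effects": list(self.main_effects),
            "affected_interactions": list(self.affected_interactions),
            "affected_only": list(self.affected_only),
            "scale_factors": dict(self.scale_factors),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DesignSpec":
        return cls(
            main_effects=tuple(d.get("main_effects", DEFAULT_MAIN_EFFECTS)),
            affected_interactions=tuple(d.get("affected_interactions", DEFAULT_AFFECTED_INTERACTIONS)),
            affected_only=tuple(d.get("affected_only", DEFAULT_AFFECTED_ONLY)),
            scale_factors=dict(d.get("scale_factors", DEFAULT_SCALE_FACTORS)),
        )


def default_design_spec() -> DesignSpec:
    """The full 20-covariates-per-muscle specification (80 columns)."""
    return DesignSpec()


def drop_terms(spec: DesignSpec, groups) -> DesignSpec:
    """Remove whole term groups ('affected_interactions' and/or 'affected_only')."""
    groups = tuple(groups)
    unknown = set(groups) - set(TERM_GROUPS)
    if unknown:
        raise SpecError(f"unknown term group(s) {sorted(unknown)}; allowed: {TERM_GROUPS}")
    out = spec
    if "affected_interactions" in groups:
        out = replace(out, affected_interactions=())
    if "affected_only" in groups:
        out = replace(out, affected_only=())
    return out


def _base_values(frame: pd.DataFrame, name: str) -> np.ndarray:
    """Series-level raw value of one design term, before scaling/interaction."""
    n = len(frame)
    if name == "intercept":
        return np.ones(n)
    if name == "elevation":
        return frame["elevation_deg"].to_numpy(dtype=float)
    if name == "move_up":
        return (frame["movement"] == "up").to_numpy(dtype=float)
    if name == "affected":
        return (frame["side"] == "affected").to_numpy(dtype=float)
    if name == "dominant":
        # measured side is the dominant hand
        if "dominant_side_measured" not in frame.columns:
            raise SpecError("design term 'dominant' needs covariate column 'dominant_side_measured'")
        dom_aff = frame["dominant_side_measured"].to_numpy(dtype=float)
        affected = (frame["side"] == "affected").to_numpy(dtype=float)
        return affected * dom_aff + (1.0 - affected) * (1.0 - dom_aff)
    col = _TERM_SOURCES.get(name, name)
    if col not in frame.columns:
        raise SpecError(f"design term {name!r} not resolvable (no column {col!r})")
    return frame[col].to_numpy(dtype=float)


@dataclass
class StackedDesign:
    """Dense stacked design: response, block design matrix, labels, layout.

    ``X`` has 4 * p columns (muscle-major); an observation has nonzero
    entries only inside its own muscle's block.  Column ``labels`` are
    ``"<muscle>.<term>"`` with interaction terms tagged ``:affected`` and
    affected-only terms ``@affected``.
    """

    X: np.ndarray
    y: np.ndarray
    labels: list
    spec: DesignSpec
    layout: SeriesLayout
    index_frame: pd.DataFrame = field(repr=False)

    @property
    def n_obs(self) -> int:
        return len(self.y)

    @property
    def n_columns(self) -> int:
        return self.X.shape[1]

    def column(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise SpecError(f"no design column labelled {label!r}") from None


def build_design(table: ObservationTable, spec: DesignSpec | None = None) -> StackedDesign:
    """Assemble the stacked design matrix from a validated table.

    Column order is deterministic: muscle-major (PM, UT, SA, RH), then the
    spec's term order within each block.  Affected-only and interaction
    columns are exactly zero on the unaffected side.
    """
    if spec is None:
        spec = default_design_spec()
    frame = table.frame
    n = len(frame)
    p = spec.p_per_muscle
    affected = (frame["side"] == "affected").to_numpy(dtype=float)

    # per-term column values, shared across muscle blocks
    cols = np.empty((n, p))
    j = 0
    for name in spec.main_effects:
        cols[:, j] = _base_values(frame, name) * spec.scale_factors.get(name, 1.0)
        j += 1
    for name in spec.affected_interactions:
        cols[:, j] = affected * _base_values(frame, name) * spec.scale_factors.get(name, 1.0)
        j += 1
    for name in spec.affected_only:
        cols[:, j] = affected * _base_values(frame, name) * spec.scale_factors.get(name, 1.0)
        j += 1

    muscle_idx = frame["muscle"].map({m: i for i, m in enumerate(MUSCLES)}).to_numpy()
    X = np.zeros((n, len(MUSCLES) * p))
    for k in range(len(MUSCLES)):
        rows = muscle_idx == k
        X[np.ix_(rows, range(k * p, (k + 1) * p))] = cols[rows]

    labels = [f"{m}.{t}" for m in MUSCLES for t in spec.terms]
    return StackedDesign(
        X=X,
        y=frame["log_emg"].to_numpy(dtype=float),
        labels=labels,
        spec=spec,
        layout=table.layout,
        index_frame=frame[["patient_id", "muscle", "side", "movement", "elevation_deg"]].copy(),
    )
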