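"""Stressor characteristics: the adjustable properties of the stimulus environment.

A characteristic is manipulated either in *discrete levels* (e.g. realism via
first- vs. third-person point of view) or on a *continuous scale* (e.g.
aversive images drawn from a rated picture set, a soundscape intensity). Every
adjustment is presented either *transient* (active for a fixed duration, then
reverted) or *state-wise* (persisting until changed again).

Continuous characteristics may be backed by a stimulus catalog: a table of
stimulus ids with affective ratings (valence/arousal/dominance for pictures and
sounds, valence/tension/energy for music). A single control scale is derived
by summing the ratings, optionally inverting selected dimensions within the
rating instrument's bounds (default 1-9, the self-assessment-manikin
convention), so that low derived values correspond to the more stressful end.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import CatalogIntegrityError, SpecError

DERIVED_SCALE = "derived_scale"

#: Default inversion flags chosen so that on the derived scale low = stressful:
#: pictures/sounds score unhappy (low valence), arousing and controlled low, so
#: arousal is inverted; music scores tense and energetic low, so tension and
#: energy are inverted.
DEFAULT_INVERSIONS = {
    ("valence", "arousal", "dominance"): {"arousal": True},
    ("valence", "tension", "energy"): {"tension": True, "energy": True},
}


@dataclass
class StimulusCatalog:
    """Rated stimulus set with an optional derived control scale.

    ``table`` holds one row per stimulus: a ``stimulus_id`` column plus one
    numeric column per rating dimension, and after :func:`derive_scale` a
    ``derived_scale`` column.
    """

    table: pd.DataFrame
    dimensions: tuple[str, ...]
    inversions: dict[str, bool] = field(default_factory=dict)
    bounds: tuple[float, float] = (1.0, 9.0)

    def __post_init__(self) -> None:
        if "stimulus_id" not in self.table.columns:
            raise CatalogIntegrityError("catalog table needs a stimulus_id column")
        missing = [d for d in self.dimensions if d not in self.table.columns]
        if missing:
            raise CatalogIntegrityError(f"catalog missing rating dimensions: {missing}")
        if self.table["stimulus_id"].duplicated().any():
            raise CatalogIntegrityError("duplicate stimulus_id in catalog")
        lo, hi = self.bounds
        if not lo < hi:
            raise CatalogIntegrityError("rating bounds must satisfy lo < hi")

    @property
    def has_scale(self) -> bool:
        return DERIVED_SCALE in self.table.columns

    @property
    def scale_range(self) -> tuple[float, float]:
        if not self.has_scale:
            raise CatalogIntegrityError("derived scale not populated; call derive_scale first")
        s = self.table[DERIVED_SCALE]
        return float(s.min()), float(s.max())

    def __len__(self) -> int:
        return len(self.table)


def derive_scale(catalog: StimulusCatalog) -> StimulusCatalog:
    """Populate the derived control scale.

    Per stimulus: sum over dimensions of the rating, with inverted dimensions
    reflected within the instrument bounds, rating -> (lo + hi - rating). With
    all inversion flags off this is the plain sum of ratings, monotone in each
    dimension.
    """
    if len(catalog) == 0:
        raise CatalogIntegrityError("catalog is empty")
    lo, hi = catalog.bounds
    total = np.zeros(len(catalog))
    for d in catalog.dimensions:
        col = catalog.table[d].to_numpy(dtype=float)
        if np.any(~np.isfinite(col)):
            raise CatalogIntegrityError(f"missing/non-finite rating in dimension {d!r}")
        total += (lo + hi - col) if catalog.inversions.get(d, False) else col
    table = catalog.table.copy()
    table[DERIVED_SCALE] = total
    return replace(catalog, table=table)


def nearest_stimulus(catalog: StimulusCatalog, x: float, exclude: tuple[str, ...] = ()) -> str:
    """Stimulus whose derived scale is closest to x.

    Ties are broken toward the lower derived scale, then lexicographically by
    stimulus id. ``exclude`` implements an optional no-repeat window: those ids
    are skipped (unless that would empty the catalog).
    """
    if not catalog.has_scale:
        raise CatalogIntegrityError("derived scale not populated; call derive_scale first")
    table = catalog.table
    if exclude:
        kept = table[~table["stimulus_id"].isin(exclude)]
        if len(kept):
            table = kept
    if not len(table):
        raise CatalogIntegrityError("catalog is empty")
    scale = table[DERIVED_SCALE].to_numpy(dtype=float)
    ids = table["stimulus_id"].astype(str).to_numpy()
    dist = np.abs(scale - float(x))
    order = np.lexsort((ids, scale, dist))  # dist, then scale, then id
    return str(ids[order[0]])


def stimulus_scale(catalog: StimulusCatalog, stimulus_id: str) -> float:
    row = catalog.table.loc[catalog.table["stimulus_id"] == stimulus_id]
    if not len(row):
        raise CatalogIntegrityError(f"unknown stimulus {stimulus_id!r}")
    return float(row[DERIVED_SCALE].iloc[0])


def enumerate_transitions(levels) -> list[tuple[str, str]]:
    """All ordered level pairs (from, to) with from != to.

    Count is L*(L-1), the number of 2-permutations of the level set. Order is
    deterministic: by from-index, then to-index, following the given level
    order.
    """
    levels = list(levels)
    if len(levels) < 2 or len(set(levels)) != len(levels):
        raise SpecError("need at least 2 distinct levels")
    return [(a, b) for a in levels for b in levels if a != b]


def make_catalog(
    n: int,
    dimensions: tuple[str, ...] = ("valence", "arousal", "dominance"),
    seed: int = 0,
    bounds: tuple[float, float] = (1.0, 9.0),
    inversions: dict[str, bool] | None = None,
) -> StimulusCatalog:
    """Synthetic rated stimulus catalog (uniform ratings over the bounds).

    Stands in for licensed affective picture/sound/music rating tables; ids
    are zero-padded (``stim_000``, ...). The derived scale is populated.
    """
    rng = np.random.default_rng(seed)
    lo, hi = bounds
    data = {"stimulus_id": [f"stim_{i:03d}" for i in range(n)]}
    for d in dimensions:
        data[d] = np.round(rng.uniform(lo, hi, size=n), 2)
    if inversions is None:
        inversions = dict(DEFAULT_INVERSIONS.get(tuple(dimensions), {}))
    cat = StimulusCatalog(pd.DataFrame(data), tuple(dimensions), inversions, bounds)
    return derive_scale(cat)


@dataclass
class CharacteristicSpec:
    """Specification of one adjustable stressor characteristic."""

    name: str
    mode: str  # "discrete" | "continuous"
    levels: tuple[str, ...] = ()
    current_level: str | None = None
    scale_range: tuple[float, float] | None = None
    catalog: StimulusCatalog | None = None
    presentation: str = "state_wise"  # "transient" | "state_wise"
    transient_duration_s: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("discrete", "continuous"):
            raise SpecError(f"unknown mode {self.mode!r}")
        if self.presentation not in ("transient", "state_wise"):
            raise SpecError(f"unknown presentation {self.presentation!r}")
        if self.mode == "discrete":
            if len(self.levels) < 2 or len(set(self.levels)) != len(self.levels):
                raise SpecError(f"{self.name}: discrete mode needs >= 2 distinct levels")
            if self.current_level is None:
                self.current_level = self.levels[0]
            if self.current_level not in self.levels:
                raise SpecError(f"{self.name}: current_level must be one of the levels")
        else:
            if self.catalog is not None and self.scale_range is None:
                self.scale_range = self.catalog.scale_range
            if self.scale_range is None or not self.scale_range[0] < self.scale_range[1]:
                raise SpecError(f"{self.name}: continuous mode needs scale_range with x_min < x_max")
        if self.presentation == "transient":
            if self.transient_duration_s is None or not self.transient_duration_s > 0:
                raise SpecError(f"{self.name}: transient presentation needs a positive duration")

    def transitions(self) -> list[tuple[str, str]]:
        return enumerate_transitions(self.levels)


@dataclass
class Adjustment:
    """One concrete stressor manipulation.

    Either a discrete level transition (from_level -> to_level) or a
    continuous value ``x`` (with the resolved ``stimulus_id`` when the
    characteristic is catalog-backed).
    """

    characteristic: str
    from_level: str | None = None
    to_level: str | None = None
    value: float | None = None
    stimulus_id: str | None = None
    presentation: str = "state_wise"
    duration_s: float | None = None
    presented_at: float | None = None

    def __post_init__(self) -> None:
        if self.is_discrete == (self.value is not None):
            raise SpecError("adjustment must carry either a level transition or a value, not both")
        if self.is_discrete and self.from_level == self.to_level:
            raise SpecError("transition levels must be distinct")
        if self.presentation == "transient" and not (self.duration_s and self.duration_s > 0):
            raise SpecError("transient adjustment needs a positive duration_s")

    @property
    def is_discrete(self) -> bool:
        return self.from_level is not None or self.to_level is not None

    @property
    def transition(self) -> tuple[str, str]:
        if not self.is_discrete:
            raise SpecError("not a discrete adjustment")
        return (self.from_level, self.to_level)

    def payload_str(self) -> str:
        if self.is_discrete:
            return f"{self.from_level}>{self.to_level}"
        return repr(float(self.value))


def clamp_to_range(x: float, scale_range: tuple[float, float]) -> float:
    lo, hi = scale_range
    return float(min(max(x, lo), hi))


def make_adjustment(spec: CharacteristicSpec, *, to_level: str | None = None, x: float | None = None,
                    presentation: str | None = None, duration_s: float | None = None) -> Adjustment:
    """Build a validated adjustment against a characteristic spec.

    Discrete: transition from the spec's current level to ``to_level``.
    Continuous: value clamped to the scale range and, when catalog-backed,
    snapped to the nearest stimulus.
    """
    pres = presentation or spec.presentation
    dur = duration_s if duration_s is not None else spec.transient_duration_s
    if spec.mode == "discrete":
        if to_level is None or to_level not in spec.levels:
            raise SpecError(f"{spec.name}: to_level must be one of {spec.levels}")
        return Adjustment(spec.name, from_level=spec.current_level, to_level=to_level,
                          presentation=pres, duration_s=dur)
    if x is None:
        raise SpecError(f"{spec.name}: continuous adjustment needs a value")
    x = clamp_to_range(float(x), spec.scale_range)
    stim = None
    if spec.catalog is not None:
        stim = nearest_stimulus(spec.catalog, x)
        x = stimulus_scale(spec.catalog, stim)
    return Adjustment(spec.name, value=x, stimulus_id=stim, presentation=pres, duration_s=dur)
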