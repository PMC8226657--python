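"""The modified Videofluoroscopic Dysphagia Scale (mVDS).

The mVDS is a 9-item weighted checklist read off a videofluoroscopic
swallowing study (VFSS). Each item is an ordered set of levels, best
condition first; each level carries a point weight, and the per-item worst
weights sum to 100, so a total score of 0 is a normal swallow and 100 the
most severe dysphagia the scale can express.

Weights are half-point granular (e.g. 11.5, 8.5). To keep sums bit-exact
they are stored internally as integers in half-point units and only
converted to float at the API surface; halves are exactly representable in
binary floating point, so exported totals are exact as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import yaml

__all__ = [
    "ScaleItem",
    "ScaleDefinition",
    "RatingProfile",
    "ProfileScore",
    "PASGrade",
    "ScaleValidationError",
    "load_scale_definition",
    "score_profile",
    "pas_to_aspiration_level",
    "MVDS_ITEM_IDS",
]


class ScaleValidationError(ValueError):
    """A scale definition, rating profile, or PAS grade failed validation."""


def _to_half_points(weight: float, where: str) -> int:
    hp = round(weight * 2)
    if abs(hp - weight * 2) > 1e-9:
        raise ScaleValidationError(
            f"{where}: weight {weight!r} is not half-point granular"
        )
    return int(hp)


@dataclass(frozen=True)
class ScaleItem:
    """One ordinal item of the scale.

    ``levels`` are ordered best→worst; ``weights`` are the points awarded
    for each level, in the same order, non-decreasing and starting at 0.
    """

    item_id: str
    label: str
    levels: tuple[str, ...]
    weights: tuple[float, ...]
    _weights_hp: tuple[int, ...] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        levels = tuple(self.levels)
        weights = tuple(float(w) for w in self.weights)
        object.__setattr__(self, "levels", levels)
        object.__setattr__(self, "weights", weights)
        if len(levels) < 2:
            raise ScaleValidationError(f"item {self.item_id!r}: needs >= 2 levels")
        if len(levels) != len(weights):
            raise ScaleValidationError(
                f"item {self.item_id!r}: {len(levels)} levels but "
                f"{len(weights)} weights"
            )
        hp = tuple(_to_half_points(w, f"item {self.item_id!r}") for w in weights)
        if hp[0] != 0:
            raise ScaleValidationError(
                f"item {self.item_id!r}: best level must carry weight 0"
            )
        if any(b < a for a, b in zip(hp, hp[1:])):
            raise ScaleValidationError(
                f"item {self.item_id!r}: weights must be non-decreasing"
            )
        object.__setattr__(self, "_weights_hp", hp)

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    @property
    def max_weight(self) -> float:
        return self.weights[-1]

    def weight_hp(self, level: int) -> int:
        """Weight of ``level`` in half-point units."""
        return self._weights_hp[level]


@dataclass(frozen=True)
class ScaleDefinition:
    """An ordered collection of :class:`ScaleItem` with a declared maximum."""

    name: str
    items: tuple[ScaleItem, ...]
    max_total: float

    def __post_init__(self) -> None:
        items = tuple(self.items)
        object.__setattr__(self, "items", items)
        if not items:
            raise ScaleValidationError("scale has no items")
        ids = [it.item_id for it in items]
        if len(set(ids)) != len(ids):
            raise ScaleValidationError(f"duplicate item ids in scale {self.name!r}")
        max_hp = sum(it._weights_hp[-1] for it in items)
        declared_hp = _to_half_points(float(self.max_total), f"scale {self.name!r}")
        if max_hp != declared_hp:
            raise ScaleValidationError(
                f"scale {self.name!r}: per-item maxima sum to {max_hp / 2}, "
                f"declared max_total is {self.max_total}"
            )

    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(it.item_id for it in self.items)

    def item(self, item_id: str) -> ScaleItem:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise KeyError(item_id)

    # -- config-file round trip -------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "max_total": float(self.max_total),
            "items": [
                {
                    "item_id": it.item_id,
                    "label": it.label,
                    "levels": list(it.levels),
                    "weights": [float(w) for w in it.weights],
                }
                for it in self.items
            ],
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False, allow_unicode=True)

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScaleDefinition":
        try:
            items = tuple(
                ScaleItem(
                    item_id=str(rec["item_id"]),
                    label=str(rec["label"]),
                    levels=tuple(str(x) for x in rec["levels"]),
                    weights=tuple(float(x) for x in rec["weights"]),
                )
                for rec in d["items"]
            )
            return cls(name=str(d["name"]), items=items, max_total=float(d["max_total"]))
        except (KeyError, TypeError) as exc:
            raise ScaleValidationError(f"malformed scale config: {exc}") from exc

    @classmethod
    def from_yaml(cls, path) -> "ScaleDefinition":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if not isinstance(d, Mapping):
            raise ScaleValidationError("malformed scale config: not a mapping")
        return cls.from_dict(d)


# Table of the mVDS: 9 items, worst-level weights summing to 100 points.
_MVDS_TABLE: tuple[tuple[str, str, tuple[str, ...], tuple[float, ...]], ...] = (
    ("lip_closure", "Lip closure", ("intact", "not intact"), (0.0, 6.0)),
    ("mastication", "Mastication", ("possible", "not possible"), (0.0, 11.5)),
    ("oral_transit_time", "Oral transit time", ("<=1.5 s", ">1.5 s"), (0.0, 4.0)),
    (
        "triggering_pharyngeal_swallow",
        "Triggering of pharyngeal swallow (swallowing reflex)",
        ("intact", "delayed"),
        (0.0, 7.0),
    ),
    ("epiglottis_inversion", "Epiglottis inversion", ("yes", "no"), (0.0, 13.0)),
    (
        "valleculae_residue",
        "Valleculae residue",
        ("0%", "<10%", ">=10%, <50%", ">=50%"),
        (0.0, 3.0, 6.0, 9.0),
    ),
    (
        "pyriformis_residue",
        "Pyriformis residue",
        ("0%", "<10%", ">=10%, <50%", ">=50%"),
        (0.0, 6.5, 13.0, 19.5),
    ),
    ("pharyngeal_wall_coating", "Pharyngeal wall coating", ("no", "yes"), (0.0, 13.0)),
    (
        "aspiration",
        "Aspiration",
        ("intact", "penetration", "aspiration"),
        (0.0, 8.5, 17.0),
    ),
)

MVDS_ITEM_IDS: tuple[str, ...] = tuple(row[0] for row in _MVDS_TABLE)


def load_scale_definition(path=None) -> ScaleDefinition:
    """Return the mVDS definition.

    With no argument the definition compiled into the package is returned.
    With ``path`` a YAML config file (as written by
    :meth:`ScaleDefinition.to_yaml`) is loaded and validated instead.
    """
    if path is not None:
        return ScaleDefinition.from_yaml(path)
    items = tuple(
        ScaleItem(item_id=i, label=lab, levels=lv, weights=w)
        for i, lab, lv, w in _MVDS_TABLE
    )
    return ScaleDefinition(name="mVDS", items=items, max_total=100.0)


def packaged_scale_config() -> "resources.abc.Traversable":
    """Path-like handle on the canonical YAML scale config shipped with the package."""
    return resources.files("mvds").joinpath("data/mvds_scale.yaml")


@dataclass(frozen=True)
class RatingProfile:
    """One rater's chosen level index (0-based, 0 = best) on every item."""

    levels: Mapping[str, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "levels", dict(self.levels))

    def validate(self, scale: ScaleDefinition) -> None:
        missing = [i for i in scale.item_ids if i not in self.levels]
        if missing:
            raise ScaleValidationError(f"profile missing items: {missing}")
        extra = [i for i in self.levels if i not in scale.item_ids]
        if extra:
            raise ScaleValidationError(f"profile has unknown items: {extra}")
        for it in scale.items:
            lev = self.levels[it.item_id]
            if not isinstance(lev, (int,)) or isinstance(lev, bool):
                raise ScaleValidationError(
                    f"item {it.item_id!r}: level index {lev!r} is not an integer"
                )
            if not 0 <= lev < it.n_levels:
                raise ScaleValidationError(
                    f"item {it.item_id!r}: level index {lev} out of range "
                    f"0..{it.n_levels - 1}"
                )

    @classmethod
    def all_best(cls, scale: ScaleDefinition) -> "RatingProfile":
        return cls({i: 0 for i in scale.item_ids})

    @classmethod
    def all_worst(cls, scale: ScaleDefinition) -> "RatingProfile":
        return cls({it.item_id: it.n_levels - 1 for it in scale.items})

    @classmethod
    def single_item(
        cls, scale: ScaleDefinition, item_id: str, level: int
    ) -> "RatingProfile":
        """All items at best level except ``item_id`` at ``level``."""
        levels = {i: 0 for i in scale.item_ids}
        levels[item_id] = level
        return cls(levels)


@dataclass(frozen=True)
class ProfileScore:
    """Total score with the per-item point breakdown (both in points)."""

    total: float
    breakdown: Mapping[str, float]


def score_profile(profile: RatingProfile, scale: ScaleDefinition) -> ProfileScore:
    """Score ``profile`` against ``scale``: the sum of the chosen levels' weights.

    The breakdown sums to the total exactly (half-point integer arithmetic
    internally), and the total lies in ``[0, scale.max_total]``.
    """
    profile.validate(scale)
    breakdown_hp = {
        it.item_id: it.weight_hp(profile.levels[it.item_id]) for it in scale.items
    }
    total_hp = sum(breakdown_hp.values())
    return ProfileScore(
        total=total_hp / 2,
        breakdown={k: v / 2 for k, v in breakdown_hp.items()},
    )


@dataclass(frozen=True)
class PASGrade:
    """Penetration–Aspiration Scale grade: ordinal 1 (no airway entry) to 8."""

    value: int

    def __post_init__(self) -> None:
        v = self.value
        if not isinstance(v, int) or isinstance(v, bool) or not 1 <= v <= 8:
            raise ScaleValidationError(f"PAS grade must be an integer in 1..8, got {v!r}")


def pas_to_aspiration_level(pas: PASGrade | int) -> int:
    """Map a PAS grade onto the mVDS aspiration item.

    PAS 1 (material does not enter the airway) → level 0 ("intact");
    PAS 2–5 (penetration above/at the vocal folds) → level 1 ("penetration");
    PAS 6–8 → level 2 ("aspiration"), matching the convention that a study is
    aspiration-positive when PAS exceeds 5.
    """
    if not isinstance(pas, PASGrade):
        pas = PASGrade(pas)
    v = pas.value
    if v == 1:
        return 0
    if v <= 5:
        return 1
    return 2


from sklearn.base import BaseEstimator, TransformerMixin  # noqa: E402
from sklearn.utils.validation import check_is_fitted  # noqa: E402


class MVDSScorer(TransformerMixin, BaseEstimator):
    """Transformer turning per-item level indices into mVDS total scores.

    Input is either a DataFrame with one column per item id or an array of
    shape ``(n, 9)`` in scale order; :meth:`transform` returns the column
    vector of totals in points, and :meth:`breakdown` the per-item points.
    Stateless apart from the scale; ``fit`` only validates.
    """

    def __init__(self, scale: ScaleDefinition | None = None):
        self.scale = scale

    def fit(self, X, y=None) -> "MVDSScorer":
        scale = self.scale if self.scale is not None else load_scale_definition()
        for p in profiles_from_frame(X, scale):
            p.validate(scale)
        self.scale_ = scale
        self.n_features_in_ = len(scale.items)
        return self

    def transform(self, X):
        import numpy as np

        check_is_fitted(self, "scale_")
        totals = [
            score_profile(p, self.scale_).total
            for p in profiles_from_frame(X, self.scale_)
        ]
        return np.asarray(totals, dtype=float).reshape(-1, 1)

    def breakdown(self, X):
        """Per-item points as a DataFrame (columns in scale order)."""
        import pandas as pd

        check_is_fitted(self, "scale_")
        rows = [
            score_profile(p, self.scale_).breakdown
            for p in profiles_from_frame(X, self.scale_)
        ]
        return pd.DataFrame(rows, columns=list(self.scale_.item_ids))


def profiles_from_frame(levels, scale: ScaleDefinition) -> list[RatingProfile]:
    """Build profiles from a table of level indices (rows=patients, cols=items)."""
    import pandas as pd

    if isinstance(levels, pd.DataFrame):
        cols = list(levels.columns)
        missing = [i for i in scale.item_ids if i not in cols]
        if missing:
            raise ScaleValidationError(f"level table missing item columns: {missing}")
        rows: Iterable = (
            {i: int(r[i]) for i in scale.item_ids} for _, r in levels.iterrows()
        )
    else:
        import numpy as np

        arr = np.asarray(levels)
        if arr.ndim != 2 or arr.shape[1] != len(scale.items):
            raise ScaleValidationError(
                f"level array must be (n, {len(scale.items)}), got {arr.shape}"
            )
        rows = ({i: int(v) for i, v in zip(scale.item_ids, row)} for row in arr)
    return [RatingProfile(r) for r in rows]
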