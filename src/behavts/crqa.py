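"""Chromatic and anisotropic cross-recurrence quantification of nominal series.

A cross-recurrence plot (CRP) of two equal-length nominal series x (horizontal
axis) and y (vertical axis) is the N×N matrix whose cell (i, j) records
whether — and in which *way* — state x_j of one partner matches state y_i of
the other. A :class:`MatchRule` defines the match categories: the default is
plain code equality (one category), but qualitatively distinct match types can
be assigned distinct signed integer categories (chromatic CRQA), e.g. +1 for
one kind of joint state and −1 for another, 0 always meaning no match.

Chromatic measures count points per category: RR_c as a fraction of all N²
cells (canonical recurrence rate) and rRR_c as a fraction of all matching
cells (relative recurrence rate).

Anisotropic measures quantify the vertical and horizontal line structures of
the (by default binarized) plot separately, capturing asymmetries in how long
each partner dwells while matched by the other: laminarity (LAM), trapping
time (TT), longest line (Max_L) and the Shannon entropy of the line-length
distribution (Ent_L), all over maximal runs of length >= l_min (default 2).
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import NominalTimeSeries
from .errors import ConfigurationError, InvalidInputError

logger = logging.getLogger(__name__)

__all__ = [
    "MatchRule",
    "CrossRecurrenceMatrix",
    "LineDistribution",
    "ChromaticRates",
    "AnisotropicMeasures",
    "build_cross_recurrence_matrix",
    "chromatic_rates",
    "line_length_distribution",
    "anisotropic_measures",
    "crqa_summary",
]


@dataclass
class MatchRule:
    """Maps ordered code pairs (x_code, y_code) to signed match categories.

    Category 0 always means "no match". ``equality_category`` switches the
    rule to plain code equality (any shared non-ignored code matches with one
    category), which is the default single-color analysis.
    """

    mapping: dict[tuple, int] = field(default_factory=dict)
    labels: dict[int, str] = field(default_factory=dict)
    colors: dict[int, str] = field(default_factory=dict)
    equality_category: int | None = None
    ignore_codes: frozenset = frozenset({0})

    def __post_init__(self):
        cats = set(self.mapping.values())
        if self.equality_category is not None:
            cats.add(self.equality_category)
        if 0 in cats:
            raise ConfigurationError("category 0 is reserved for no-match")
        for c in cats:
            self.labels.setdefault(c, f"category {c}")

    @classmethod
    def equality(cls, category: int = 1, label: str = "match") -> "MatchRule":
        return cls(labels={category: label}, equality_category=category)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "MatchRule":
        """Build a rule from a table with columns x_code,y_code,category
        (optionally label, color)."""
        required = {"x_code", "y_code", "category"}
        if not required.issubset(frame.columns):
            raise ConfigurationError(
                f"match-rule table needs columns {sorted(required)}"
            )
        mapping, labels, colors = {}, {}, {}
        for _, row in frame.iterrows():
            cat = int(row["category"])
            mapping[(int(row["x_code"]), int(row["y_code"]))] = cat
            if "label" in frame.columns and not pd.isna(row.get("label")):
                labels[cat] = str(row["label"])
            if "color" in frame.columns and not pd.isna(row.get("color")):
                colors[cat] = str(row["color"])
        return cls(mapping=mapping, labels=labels, colors=colors)

    @classmethod
    def from_csv(cls, path) -> "MatchRule":
        return cls.from_frame(pd.read_csv(path))

    @property
    def categories(self) -> list[int]:
        if self.equality_category is not None:
            return [self.equality_category]
        return sorted(set(self.mapping.values()))

    def __call__(self, x_code, y_code) -> int:
        if self.equality_category is not None:
            return (
                self.equality_category
                if x_code == y_code and x_code not in self.ignore_codes
                else 0
            )
        return self.mapping.get((x_code, y_code), 0)


@dataclass
class CrossRecurrenceMatrix:
    """N×N integer matrix; rec[i, j] = rule(x_j, y_i)."""

    rec: np.ndarray
    rule: MatchRule
    x_label: str = ""
    y_label: str = ""

    @property
    def n(self) -> int:
        return self.rec.shape[0]

    def binarized(self) -> np.ndarray:
        return self.rec != 0

    def transposed(self) -> "CrossRecurrenceMatrix":
        return CrossRecurrenceMatrix(
            self.rec.T.copy(), self.rule, x_label=self.y_label, y_label=self.x_label
        )


@dataclass
class LineDistribution:
    """Counts of maximal run lengths along one orientation of the CRP."""

    orientation: str  # "vertical" | "horizontal"
    counts: Counter
    l_min: int = 2

    @property
    def total_points(self) -> int:
        return sum(l * c for l, c in self.counts.items())

    def qualifying(self) -> dict[int, int]:
        return {l: c for l, c in self.counts.items() if l >= self.l_min}


@dataclass
class ChromaticRates:
    rr: dict[int, float]  # per category, fraction of N^2
    rrr: dict[int, float] | None  # per category, fraction of matches (None if none)
    total_rr: float

    def to_frame(self) -> pd.DataFrame:
        cats = sorted(self.rr)
        return pd.DataFrame(
            {
                "category": cats,
                "RR": [self.rr[c] for c in cats],
                "rRR": [self.rrr[c] if self.rrr else math.nan for c in cats],
            }
        )


@dataclass
class AnisotropicMeasures:
    orientation: str
    lam: float | None
    tt: float | None
    max_l: int | None
    ent_l: float | None

    def to_dict(self) -> dict:
        return {
            "orientation": self.orientation,
            "LAM": self.lam,
            "TT": self.tt,
            "Max_L": self.max_l,
            "Ent_L": self.ent_l,
        }


def build_cross_recurrence_matrix(
    x: NominalTimeSeries, y: NominalTimeSeries, rule: MatchRule | None = None
) -> CrossRecurrenceMatrix:
    """Construct the chromatic cross-recurrence matrix of two nominal series.

    The horizontal axis (columns) indexes ``x``, the vertical axis (rows)
    indexes ``y``. Unequal lengths are an error — trim upstream if intended.
    Codes absent from an explicit mapping rule are treated as no-match with a
    logged warning.
    """
    rule = rule or MatchRule.equality()
    xv, yv = x.values, y.values
    if len(xv) != len(yv):
        raise InvalidInputError(
            f"series lengths differ ({len(xv)} vs {len(yv)}); no implicit trimming"
        )
    n = len(xv)
    rec = np.zeros((n, n), dtype=int)
    if rule.equality_category is not None:
        for c in np.unique(np.concatenate([xv, yv])):
            if c in rule.ignore_codes:
                continue
            rec[np.ix_(yv == c, xv == c)] = rule.equality_category
    else:
        known_x = {k[0] for k in rule.mapping}
        known_y = {k[1] for k in rule.mapping}
        unknown = (set(np.unique(xv)) - known_x - {0}) | (
            set(np.unique(yv)) - known_y - {0}
        )
        if unknown:
            logger.warning(
                "codes %s not covered by the match rule; treated as no-match",
                sorted(unknown),
            )
        for (xc, yc), cat in rule.mapping.items():
            rec[np.ix_(yv == yc, xv == xc)] = cat
    return CrossRecurrenceMatrix(rec, rule, x_label=x.label, y_label=y.label)


def chromatic_rates(crm: CrossRecurrenceMatrix) -> ChromaticRates:
    """Per-category canonical (RR) and relative (rRR) recurrence rates."""
    n_cells = crm.rec.size
    cats = sorted(set(np.unique(crm.rec)) - {0}) or crm.rule.categories
    counts = {c: int((crm.rec == c).sum()) for c in cats}
    n_matches = sum(counts.values())
    rr = {c: counts[c] / n_cells for c in cats}
    rrr = {c: counts[c] / n_matches for c in cats} if n_matches else None
    return ChromaticRates(rr=rr, rrr=rrr, total_rr=n_matches / n_cells)


def _run_lengths_by_column(mask: np.ndarray) -> Counter:
    """Lengths of maximal vertical (within-column) runs of True."""
    n_rows, n_cols = mask.shape
    padded = np.zeros((n_rows + 1, n_cols), dtype=bool)
    padded[:n_rows] = mask
    flat = padded.ravel(order="F")  # column-major; padding row breaks columns
    changes = np.flatnonzero(np.diff(np.concatenate(([False], flat, [False])).astype(np.int8)))
    starts, ends = changes[::2], changes[1::2]
    return Counter((ends - starts).tolist())


def line_length_distribution(
    crm: CrossRecurrenceMatrix,
    orientation: str,
    binarize: bool = True,
    category: int | None = None,
    l_min: int = 2,
) -> LineDistribution:
    """Distribution of maximal vertical or horizontal line lengths.

    ``binarize=True`` collapses all non-zero categories before scanning —
    the default quantitative analysis treats all match types as equal.
    ``category`` restricts the scan to one match category instead.
    Vertical runs scan each column over consecutive rows; horizontal runs
    scan each row over consecutive columns. No wrap-around, no edge
    correction.
    """
    if orientation not in ("vertical", "horizontal"):
        raise ConfigurationError(f"unknown orientation {orientation!r}")
    if category is not None:
        mask = crm.rec == category
    elif binarize:
        mask = crm.binarized()
    else:
        raise ConfigurationError("pass binarize=True or an explicit category")
    if orientation == "horizontal":
        mask = mask.T
    return LineDistribution(orientation, _run_lengths_by_column(mask), l_min=l_min)


def _measures_from_distribution(dist: LineDistribution) -> AnisotropicMeasures:
    total = dist.total_points
    qual = dist.qualifying()
    if not qual or total == 0:
        return AnisotropicMeasures(dist.orientation, None, None, None, None)
    qual_points = sum(l * c for l, c in qual.items())
    qual_lines = sum(qual.values())
    lam = qual_points / total
    tt = qual_points / qual_lines
    max_l = max(qual)
    probs = np.array([c / qual_lines for c in qual.values()])
    ent = float(-(probs * np.log(probs)).sum())
    return AnisotropicMeasures(dist.orientation, lam, tt, max_l, ent)


def anisotropic_measures(
    crm: CrossRecurrenceMatrix,
    l_min: int = 2,
    category: int | None = None,
) -> tuple[AnisotropicMeasures, AnisotropicMeasures]:
    """LAM / TT / Max_L / Ent_L for the vertical and horizontal orientations.

    LAM's denominator counts all recurrent points (runs of any length >= 1);
    TT, Max_L and Ent_L are computed over qualifying runs (length >= l_min)
    only. When no qualifying lines exist all measures are reported missing.
    """
    kwargs = dict(category=category) if category is not None else dict(binarize=True)
    vert = line_length_distribution(crm, "vertical", l_min=l_min, **kwargs)
    horiz = line_length_distribution(crm, "horizontal", l_min=l_min, **kwargs)
    return _measures_from_distribution(vert), _measures_from_distribution(horiz)


@dataclass
class CRQAResult:
    chromatic: ChromaticRates
    vertical: AnisotropicMeasures
    horizontal: AnisotropicMeasures
    per_category: dict[int, tuple[AnisotropicMeasures, AnisotropicMeasures]] | None = None
    matrix: CrossRecurrenceMatrix | None = None

    def anisotropic_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.vertical.to_dict(), self.horizontal.to_dict()])


def crqa_summary(
    x: NominalTimeSeries,
    y: NominalTimeSeries,
    rule: MatchRule | None = None,
    l_min: int = 2,
    per_category: bool = False,
    keep_matrix: bool = True,
) -> CRQAResult:
    """One-call chromatic + anisotropic CRQA of a dyad.

    Returns the per-category recurrence rates, the binarized vertical and
    horizontal line measures, and (optionally) the line measures of each
    match category separately.
    """
    crm = build_cross_recurrence_matrix(x, y, rule)
    chrom = chromatic_rates(crm)
    vert, horiz = anisotropic_measures(crm, l_min=l_min)
    per_cat = None
    if per_category:
        per_cat = {
            c: anisotropic_measures(crm, l_min=l_min, category=c)
            for c in sorted(set(np.unique(crm.rec)) - {0})
        }
    return CRQAResult(
        chromatic=chrom,
        vertical=vert,
        horizontal=horiz,
        per_category=per_cat,
        matrix=crm if keep_matrix else None,
    )
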