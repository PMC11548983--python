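"""Trapezoidal membership functions, fuzzy partitions and fuzzification.

A partition splits one lab parameter's axis into an ordered set of linguistic
categories (default LOW / NORMAL / HIGH).  Adjacent categories share a linear
transition band in which the two memberships are complementary, so at every
point of the universe the degrees sum to one (a "partition of unity").  This
makes the downstream disease scores directly interpretable and reduces to
classical crisp categorisation when the band widths shrink to zero.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import CalibrationError, ConfigurationError
from .labels import LabParameter

logger = logging.getLogger(__name__)

DEFAULT_CATEGORIES = ("LOW", "NORMAL", "HIGH")


@dataclass(frozen=True)
class MembershipFunction:
    """Trapezoid with breakpoints a <= b <= c <= d (triangle when b == c).

    mu = 0 outside (a, d), mu = 1 on [b, c], linear on (a, b) and (c, d).
    Shoulder shapes (a == b or c == d) represent the outermost categories.
    """

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if not (self.a <= self.b <= self.c <= self.d):
            raise ConfigurationError(
                f"breakpoints must be ordered a<=b<=c<=d, got "
                f"({self.a}, {self.b}, {self.c}, {self.d})"
            )
        if not all(math.isfinite(v) for v in (self.a, self.b, self.c, self.d)):
            raise ConfigurationError("breakpoints must be finite")

    @classmethod
    def trapezoid(cls, a: float, b: float, c: float, d: float) -> "MembershipFunction":
        return cls(a, b, c, d)

    @classmethod
    def triangle(cls, a: float, b: float, c: float) -> "MembershipFunction":
        return cls(a, b, b, c)

    @property
    def shape(self) -> str:
        return "triangle" if self.b == self.c else "trapezoid"

    def __call__(self, x: float) -> float:
        """Piecewise-linear membership degree; total on all finite x."""
        if self.b <= x <= self.c:
            return 1.0
        if self.a < x < self.b:
            return (x - self.a) / (self.b - self.a)
        if self.c < x < self.d:
            return (self.d - x) / (self.d - self.c)
        return 0.0

    def breakpoints(self) -> tuple[float, float, float, float]:
        return (self.a, self.b, self.c, self.d)


@dataclass(frozen=True)
class FuzzifiedValue:
    """A crisp lab value translated into per-category membership degrees."""

    parameter: LabParameter
    value: float
    degrees: Mapping[str, float]

    def degree(self, category: str) -> float:
        return self.degrees.get(category, 0.0)

    def support(self, threshold: float = 0.0) -> list[str]:
        """Categories with degree strictly above ``threshold``, in label order."""
        return [c for c, d in self.degrees.items() if d > threshold]


@dataclass(frozen=True)
class FuzzyPartition:
    """Ordered linguistic categories covering one parameter's universe.

    Structural contract (checked at construction): the first function is a
    left shoulder starting at the universe edge, the last a right shoulder
    ending at it, and each adjacent pair shares its transition band exactly
    (``terms[i]`` falls on [c_i, d_i] while ``terms[i+1]`` rises on the same
    interval), which guarantees the partition-of-unity property.
    """

    parameter: LabParameter
    terms: tuple[tuple[str, MembershipFunction], ...]
    universe: tuple[float, float]

    def __post_init__(self) -> None:
        if len(self.terms) < 2:
            raise ConfigurationError("a partition needs at least two categories")
        lo, hi = self.universe
        if not (lo < hi):
            raise ConfigurationError("universe must have positive width")
        labels = [t[0] for t in self.terms]
        if len(set(labels)) != len(labels):
            raise ConfigurationError(f"duplicate category labels: {labels}")
        first, last = self.terms[0][1], self.terms[-1][1]
        if not (first.a == first.b == lo):
            raise ConfigurationError(
                f"{self.parameter.value}: first category must be a left shoulder "
                f"anchored at the universe edge {lo}"
            )
        if not (last.c == last.d == hi):
            raise ConfigurationError(
                f"{self.parameter.value}: last category must be a right shoulder "
                f"anchored at the universe edge {hi}"
            )
        for (lab_lo, mf_lo), (lab_hi, mf_hi) in zip(self.terms, self.terms[1:]):
            if not (mf_lo.c == mf_hi.a and mf_lo.d == mf_hi.b):
                raise ConfigurationError(
                    f"{self.parameter.value}: categories {lab_lo!r} and {lab_hi!r} "
                    "must share a complementary transition band "
                    f"(got fall [{mf_lo.c}, {mf_lo.d}] vs rise [{mf_hi.a}, {mf_hi.b}])"
                )

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(t[0] for t in self.terms)

    def function(self, category: str) -> MembershipFunction:
        for lab, mf in self.terms:
            if lab == category:
                return mf
        raise KeyError(category)

    def transition_band(self, boundary_index: int) -> tuple[float, float]:
        """The shared band between terms ``boundary_index`` and the next one."""
        mf = self.terms[boundary_index][1]
        return (mf.c, mf.d)

    def fuzzify(self, x: float) -> FuzzifiedValue:
        """Translate a crisp value into degrees for every category.

        Values outside the universe are clamped to its edges with a warning:
        pathology reports do contain extreme but real values.
        """
        if not math.isfinite(x):
            raise ConfigurationError(f"cannot fuzzify non-finite value {x}")
        lo, hi = self.universe
        if x < lo or x > hi:
            clamped = min(max(x, lo), hi)
            logger.warning(
                "%s value %s outside universe [%s, %s]; clamped to %s",
                self.parameter.value, x, lo, hi, clamped,
            )
            x = clamped
        degrees = {lab: mf(x) for lab, mf in self.terms}
        return FuzzifiedValue(self.parameter, x, degrees)

    def crisp_categorize(self, x: float) -> str:
        """Argmax-degree category; exact ties go to the lower-indexed label."""
        fv = self.fuzzify(x)
        best_label, best_degree = None, -1.0
        for lab in self.labels:  # label order => deterministic tie-break
            if fv.degrees[lab] > best_degree:
                best_label, best_degree = lab, fv.degrees[lab]
        assert best_label is not None
        return best_label


def eval_membership(mf: MembershipFunction, x: float) -> float:
    """Functional alias for ``mf(x)``."""
    return mf(x)


def fuzzify_value(x: float, partition: FuzzyPartition) -> FuzzifiedValue:
    return partition.fuzzify(x)


def crisp_categorize(x: float, partition: FuzzyPartition) -> str:
    return partition.crisp_categorize(x)


@dataclass(frozen=True)
class CategoryCombination:
    """One joint assignment of a category per parameter, with its possibility
    (the minimum of the member degrees)."""

    categories: tuple[tuple[LabParameter, str], ...]
    possibility: float

    def as_dict(self) -> dict[LabParameter, str]:
        return dict(self.categories)


def candidate_category_combinations(
    fuzzified: Mapping[LabParameter, FuzzifiedValue],
    threshold: float = 0.0,
) -> list[CategoryCombination]:
    """Enumerate joint category assignments supported by the fuzzified inputs.

    Cartesian product of each parameter's categories with degree strictly above
    ``threshold``, ordered by joint possibility (min of degrees) descending;
    ties resolve by category order.  With the worked two-parameter example
    (RDW split 0.8/0.2, MCV split 0.3/0.7) this yields four combinations, where
    a crisp categoriser would admit exactly one.
    """
    if not (0.0 <= threshold < 1.0):
        raise ValueError(f"threshold must be in [0, 1), got {threshold}")
    params = list(fuzzified)
    per_param: list[list[tuple[str, float]]] = []
    for p in params:
        fv = fuzzified[p]
        cats = [(c, fv.degrees[c]) for c in fv.degrees if fv.degrees[c] > threshold]
        per_param.append(cats)
    combos = []
    for choice in itertools.product(*per_param):
        cats = tuple((p, c) for p, (c, _) in zip(params, choice))
        possibility = min((d for _, d in choice), default=1.0)
        combos.append(CategoryCombination(cats, possibility))
    combos.sort(key=lambda c: -c.possibility)
    return combos


def calibrate_transition(
    partition: FuzzyPartition,
    boundary_index: int,
    anchor_x: float,
    anchor_degree: float,
    *,
    mode: str = "fix_start",
    width: float | None = None,
) -> FuzzyPartition:
    """Re-solve one transition band so it passes through a published anchor.

    The anchor states the degree of the *lower* category at ``anchor_x``
    within the band between terms ``boundary_index`` and ``boundary_index+1``.
    Two modes:

    - ``fix_start``: keep the band start (lower plateau end) and solve the
      band end, e.g. an RDW LOW->NORMAL band starting at 10.0 anchored at
      (10.5, 0.8) ends at 12.5.
    - ``fix_width``: keep the band width (``width`` required) and slide the
      band, e.g. an MCV band of width 5.0 anchored at (80.0, 0.3) becomes
      [76.5, 81.5].

    All other breakpoints are untouched; the complementary upper term is
    adjusted identically so the partition-of-unity property is preserved.
    """
    if not (0.0 < anchor_degree < 1.0):
        raise CalibrationError(
            f"anchor degree must be in (0, 1), got {anchor_degree}"
        )
    if not (0 <= boundary_index < len(partition.terms) - 1):
        raise CalibrationError(f"no transition band at index {boundary_index}")
    start, end = partition.transition_band(boundary_index)
    if mode == "fix_start":
        # lower-term degree (end - x) / (end - start) = anchor_degree
        new_start = start
        new_end = (anchor_x - anchor_degree * start) / (1.0 - anchor_degree)
    elif mode == "fix_width":
        if width is None:
            width = end - start
        if width <= 0:
            raise CalibrationError("band width must be positive")
        new_end = anchor_x + anchor_degree * width
        new_start = new_end - width
    else:
        raise ValueError(f"unknown calibration mode {mode!r}")

    lower = partition.terms[boundary_index][1]
    upper = partition.terms[boundary_index + 1][1]
    if not (lower.b <= new_start < new_end <= upper.c):
        raise CalibrationError(
            f"anchor ({anchor_x}, {anchor_degree}) gives infeasible band "
            f"[{new_start:g}, {new_end:g}] between plateaus ending {lower.b} "
            f"and starting {upper.c}"
        )
    logger.warning(
        "calibrated %s band %d to [%g, %g] from anchor (%g, %g)",
        partition.parameter.value, boundary_index, new_start, new_end,
        anchor_x, anchor_degree,
    )
    terms = list(partition.terms)
    terms[boundary_index] = (
        terms[boundary_index][0],
        MembershipFunction(lower.a, lower.b, new_start, new_end),
    )
    terms[boundary_index + 1] = (
        terms[boundary_index + 1][0],
        MembershipFunction(new_start, new_end, upper.c, upper.d),
    )
    return FuzzyPartition(partition.parameter, tuple(terms), partition.universe)
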