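"""Estimation-sample construction: forest definition, outcome coding,
spaced random sampling, and exclusion rules.

The estimation frame starts from a pixel table of 30 m cells, keeps cells
that were forest in 2000 (tree cover strictly above a cutoff, 10% by
default with a 25% sensitivity setting), draws a random 1% sample, thins
spatially adjacent observations, and applies the study's exclusion rules.
Pixels in the unprotected parts of protected properties are not discarded:
they are routed to a separate spillover pool, where they later serve as
the treated units of the leakage analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple, Union

import numpy as np
import pandas as pd

EXCLUDED = "excluded"

SPILLOVER_RULE = "unprotected_parts_of_protected_properties"

#: Recognised exclusion rules, in canonical application order.
KNOWN_RULES = (
    "urban",
    "water",
    "mangrove",
    "post2000_protection",
    "comunidades",
    "named_excluded_properties",
    SPILLOVER_RULE,
)


class RuleError(ValueError):
    """Unknown exclusion rule name."""


def define_forest(tree_cover_pct: Union[float, np.ndarray],
                  cutoff: float = 10.0):
    """Forest in 2000 iff percent tree cover strictly exceeds the cutoff."""
    arr = np.asarray(tree_cover_pct, dtype=float)
    if np.any(arr < 0) or np.any(arr > 100):
        raise ValueError("tree cover percent must lie in [0, 100]")
    out = arr > cutoff
    return bool(out) if np.isscalar(tree_cover_pct) else out


def code_outcome(forested_2000: bool, cleared_2000_2014: bool):
    """Binary loss outcome; non-forest pixels are excluded outright."""
    if not forested_2000:
        return EXCLUDED
    return 1 if cleared_2000_2014 else 0


@dataclass
class ExclusionLog:
    """Ordered per-rule bookkeeping of removed (or rerouted) pixels."""

    n_input: int
    entries: List[Tuple[str, int]] = field(default_factory=list)

    def add(self, rule: str, n_removed: int) -> None:
        self.entries.append((rule, int(n_removed)))

    @property
    def n_removed_total(self) -> int:
        return sum(n for _, n in self.entries)

    @property
    def n_output(self) -> int:
        return self.n_input - self.n_removed_total

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["rule", "n_removed"])


def draw_sample(pixels: pd.DataFrame, fraction: float = 0.01,
                min_spacing_m: float = 30.0, seed: int = 0,
                ) -> Tuple[pd.DataFrame, ExclusionLog]:
    """Random pixel sample with a minimum-spacing (adjacency) rule.

    Each forested pixel is retained independently with probability
    ``fraction`` (so the retained count is Binomial), then pairs closer
    than ``min_spacing_m`` — Chebyshev distance on the 30 m grid, i.e. the
    8-neighborhood for 30 m — are thinned greedily in a seeded random
    order. Deterministic given ``seed``; when an integer ``pixel_id``
    column is present the retention draw is keyed to the pixel id, so
    nested forest definitions (e.g. a higher tree-cover cutoff) yield
    nested pre-thinning samples.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    if len(pixels) == 0:
        raise ValueError("empty forested pixel set")
    rng = np.random.default_rng(seed)
    log = ExclusionLog(n_input=len(pixels))

    if fraction >= 1:
        keep = np.ones(len(pixels), dtype=bool)
    elif ("pixel_id" in pixels
          and pd.api.types.is_integer_dtype(pixels["pixel_id"])
          and 0 <= pixels["pixel_id"].min()
          and pixels["pixel_id"].max() < 5 * 10**7):
        ids = pixels["pixel_id"].to_numpy()
        u = np.random.default_rng(seed).random(int(ids.max()) + 1)
        keep = u[ids] < fraction
    else:
        keep = rng.random(len(pixels)) < fraction
    sampled = pixels[keep]
    log.add("not_sampled", len(pixels) - len(sampled))

    rad = int(min_spacing_m // 30)
    if rad >= 1 and len(sampled) > 1:
        order = rng.permutation(len(sampled))
        rows = sampled["row"].to_numpy()
        cols = sampled["col"].to_numpy()
        occupied = set()
        keep_mask = np.zeros(len(sampled), dtype=bool)
        offsets = [(dr, dc) for dr in range(-rad, rad + 1)
                   for dc in range(-rad, rad + 1)]
        for i in order:
            r, c = int(rows[i]), int(cols[i])
            if any((r + dr, c + dc) in occupied for dr, dc in offsets):
                continue
            occupied.add((r, c))
            keep_mask[i] = True
        thinned = sampled[keep_mask]
        log.add("spacing", len(sampled) - len(thinned))
        sampled = thinned
    else:
        log.add("spacing", 0)
    return sampled, log


def apply_exclusions(sample: pd.DataFrame,
                     rules: Sequence[str] = KNOWN_RULES,
                     excluded_property_names: Sequence[str] = (),
                     ) -> Tuple[pd.DataFrame, pd.DataFrame, ExclusionLog]:
    """Apply the named exclusion rules in their declared order.

    Rules act on optional flag columns of the pixel table (a rule whose
    column is absent removes nothing): ``urban`` and ``water`` boolean
    columns; ``mangrove`` via ``biome == "mangrove"``;
    ``post2000_protection`` boolean column; ``comunidades`` via
    ``tenure == "comunidad"``; ``named_excluded_properties`` via a
    ``property_name`` column matched against *excluded_property_names*.
    The spillover rule does not discard: pixels in unprotected parts of
    protected properties are returned as a separate pool.

    Returns ``(main sample, spillover pool, log)``.
    """
    for rule in rules:
        if rule not in KNOWN_RULES:
            raise RuleError(f"unknown exclusion rule: {rule}")
    log = ExclusionLog(n_input=len(sample))
    out = sample
    spillover = sample.iloc[0:0]
    for rule in rules:
        if rule == "urban" and "urban" in out:
            mask = out["urban"].astype(bool)
        elif rule == "water" and "water" in out:
            mask = out["water"].astype(bool)
        elif rule == "mangrove":
            mask = out["biome"] == "mangrove"
        elif rule == "post2000_protection" and "post2000_protected" in out:
            mask = out["post2000_protected"].astype(bool)
        elif rule == "comunidades":
            mask = out["tenure"] == "comunidad"
        elif rule == "named_excluded_properties" and "property_name" in out:
            mask = out["property_name"].isin(excluded_property_names)
        elif rule == SPILLOVER_RULE:
            mask = (out["protection_class"]
                    == "unprotected_part_of_protected_property")
            spillover = out[mask]
            log.add(rule, int(mask.sum()))
            out = out[~mask]
            continue
        else:
            mask = pd.Series(False, index=out.index)
        log.add(rule, int(mask.sum()))
        out = out[~mask.to_numpy()]
    return out, spillover, log


@dataclass
class StudyFrame:
    """Built estimation frame: main sample, spillover pool, bookkeeping."""

    sample: pd.DataFrame
    spillover_pool: pd.DataFrame
    sample_log: ExclusionLog
    exclusion_log: ExclusionLog
    cutoff: float


def build_frame(pixels: pd.DataFrame, cutoff: float = 10.0,
                fraction: float = 0.01, min_spacing_m: float = 30.0,
                seed: int = 0,
                rules: Sequence[str] = KNOWN_RULES,
                excluded_property_names: Sequence[str] = ()) -> StudyFrame:
    """Forest filter -> spaced random sample -> exclusion rules."""
    forested = pixels
    if "forest_cover_2000_pct" in pixels:
        forested = pixels[define_forest(
            pixels["forest_cover_2000_pct"].to_numpy(), cutoff)]
    if len(forested) == 0:
        raise ValueError("no forested pixels at this cutoff")
    sampled, sample_log = draw_sample(forested, fraction=fraction,
                                      min_spacing_m=min_spacing_m, seed=seed)
    main, spill, excl_log = apply_exclusions(
        sampled, rules, excluded_property_names)
    return StudyFrame(sample=main, spillover_pool=spill,
                      sample_log=sample_log, exclusion_log=excl_log,
                      cutoff=cutoff)
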