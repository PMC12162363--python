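"""Diversity surfaces from stacked binary ranges.

SR(cell) is the count of species present; WE(cell) = Σ 1/C_i over present
species, with C_i species i's total occupied cell count — so WE sums to the
species count over the whole landscape; CWE = WE/SR, defined only where
SR > 0 (nodata elsewhere). Stacks can be stratified by Red List group with
range sizes C_i always taken from the full ranges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import GridRaster, assert_aligned
from .sdm import BinaryRange

#: Red List groups mapped as in threat-status stratified diversity maps.
CATEGORY_GROUPS = {"ENVU": ("EN", "VU", "CR"), "NT": ("NT",), "LC": ("LC",)}
KNOWN_CATEGORIES = {"CR", "EN", "VU", "NT", "LC", "DD"}


@dataclass
class DiversityStack:
    sr: GridRaster
    we: GridRaster
    cwe: GridRaster
    group: str = "ALL"


def _presence_stack(ranges: dict[str, BinaryRange]) -> tuple[np.ndarray, GridRaster, list[str]]:
    if not ranges:
        raise ValueError("empty range list")
    species = sorted(ranges)
    grids = [ranges[sp].presence for sp in species]
    assert_aligned(*grids)
    stack = np.stack([np.nan_to_num(g.values) for g in grids])
    return stack, grids[0], species


def richness(ranges: dict[str, BinaryRange]) -> GridRaster:
    """Species richness: per-cell count of species with presence 1."""
    stack, template, _ = _presence_stack(ranges)
    return template.like(stack.sum(axis=0))


def weighted_endemism(ranges: dict[str, BinaryRange],
                      full_ranges: dict[str, BinaryRange] | None = None) -> GridRaster:
    """WE = Σ_present 1/C_i; C_i from ``full_ranges`` when stratifying."""
    stack, template, species = _presence_stack(ranges)
    sizes = np.array([(full_ranges or ranges)[sp].range_cells for sp in species], dtype=float)
    if (sizes == 0).any():
        raise ValueError("species with an empty range in WE computation")
    return template.like(np.tensordot(1.0 / sizes, stack, axes=1))


def corrected_weighted_endemism(sr: GridRaster, we: GridRaster) -> GridRaster:
    """CWE = WE/SR where SR > 0; nodata where SR = 0."""
    assert_aligned(sr, we)
    with np.errstate(invalid="ignore", divide="ignore"):
        cwe = np.where(sr.values > 0, we.values / sr.values, np.nan)
    return sr.like(cwe)


def diversity_stack(ranges: dict[str, BinaryRange], group: str = "ALL",
                    full_ranges: dict[str, BinaryRange] | None = None) -> DiversityStack:
    sr = richness(ranges)
    we = weighted_endemism(ranges, full_ranges)
    return DiversityStack(sr, we, corrected_weighted_endemism(sr, we), group)


def stratify(ranges: dict[str, BinaryRange],
             categories: pd.Series | dict) -> dict[str, DiversityStack]:
    """Per-Red-List-group stacks (ENVU, NT, LC) plus the ALL stack.

    ``categories`` maps species → category. Range sizes entering WE are the
    species' full range sizes regardless of group.
    """
    categories = dict(categories)
    unknown = set(categories.values()) - KNOWN_CATEGORIES
    if unknown:
        raise ValueError(f"unknown Red List categories: {sorted(unknown)}")
    out = {"ALL": diversity_stack(ranges, "ALL")}
    template = next(iter(ranges.values())).presence
    for group, cats in CATEGORY_GROUPS.items():
        subset = {sp: r for sp, r in ranges.items() if categories.get(sp) in cats}
        if not subset:
            warnings.warn(f"stratify: no species in group {group}")
            nan = template.like(np.full(template.shape, np.nan))
            out[group] = DiversityStack(nan, nan, nan, group)
            continue
        out[group] = diversity_stack(subset, group, full_ranges=ranges)
    return out
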