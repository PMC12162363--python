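"""Published regional figures for the south subtropical-tropical zone of
China (STZC) freshwater-crab fauna, and the bookkeeping derived from them.

These are inputs (areas, counts, Red List tallies) from the study region's
reserve register and taxonomic compilations, kept in one place so reports
derive percentages from the primitive numbers instead of hard-coding them.
"""

from __future__ import annotations

from scipy.stats import norm

#: Total STZC land area and the combined area of its nature reserves (km²).
STZC_LAND_AREA_KM2 = 563_710.0
STZC_RESERVE_AREA_KM2 = 31_888.0

#: Fauna: genera/species in the STZC vs all of China; endemics to China.
STZC_GENERA, CHINA_GENERA = 45, 62
STZC_SPECIES, CHINA_SPECIES = 195, 377
STZC_ENDEMIC_SPECIES = 186

#: Threat status: species at risk among the non-data-deficient assessments.
STZC_THREATENED, STZC_NON_DD = 41, 182

#: Red List re-assessment bookkeeping: uplisted, downlisted, newly DD, and
#: formerly-DD species given a status (the latter split EN/VU/LC/NT).
REDLIST_UPLISTED, REDLIST_DOWNLISTED, REDLIST_TO_DD = 8, 6, 3
REDLIST_FROM_DD = {"EN": 2, "VU": 8, "LC": 30, "NT": 25}

#: Proposed reserve-expansion share of the STZC (first CPA increment).
EXPANSION_FRACTION = 0.093


def reserve_coverage_pct() -> float:
    """Reserve share of the STZC land area, in percent."""
    return 100.0 * STZC_RESERVE_AREA_KM2 / STZC_LAND_AREA_KM2


def genera_share_pct() -> float:
    return 100.0 * STZC_GENERA / CHINA_GENERA


def species_share_pct() -> float:
    return 100.0 * STZC_SPECIES / CHINA_SPECIES


def endemic_share_pct() -> float:
    return 100.0 * STZC_ENDEMIC_SPECIES / STZC_SPECIES


def threatened_share_pct() -> float:
    return 100.0 * STZC_THREATENED / STZC_NON_DD


def redlist_changed_total() -> int:
    """Species whose status changed in the re-assessment."""
    return (REDLIST_UPLISTED + REDLIST_DOWNLISTED + REDLIST_TO_DD
            + sum(REDLIST_FROM_DD.values()))


def redlist_from_dd_total() -> int:
    return sum(REDLIST_FROM_DD.values())


def expansion_area_km2() -> float:
    """Absolute area of the proposed first reserve expansion."""
    return EXPANSION_FRACTION * STZC_LAND_AREA_KM2


def hotspot_z_thresholds() -> tuple[float, float, float]:
    """Two-sided standard-normal quantiles at 90/95/99% confidence.

    These round to the conventional hotspot class bounds 1.65/1.96/2.58.
    """
    return tuple(float(norm.ppf(1 - a / 2)) for a in (0.10, 0.05, 0.01))


def hotspot_class_bounds() -> tuple[float, float, float]:
    """The class bounds as conventionally printed: quantiles rounded
    half-up at three then two decimals (1.6449 → 1.645 → 1.65)."""
    from decimal import ROUND_HALF_UP, Decimal

    out = []
    for q in hotspot_z_thresholds():
        d = Decimal(f"{q:.3f}").quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)
        out.append(float(d))
    return tuple(out)
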