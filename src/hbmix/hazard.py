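"""Hazard quotients and community hazard indices.

The toxicity-weighting core: each biomarker concentration is divided
by its guidance value to give a hazard quotient

    HQ_ij = C_ij / HBGV_i

for individual j and mixture component i, with the concentration
converted to the guidance value's units first (creatinine-corrected
concentrations where the guidance value is creatinine-standardized).
Under dose additivity the hazard index of a mixture is the sum of its
components' quotients, HI_j = sum_i HQ_ij; HQ or HI strictly greater
than 1 flags a potential health concern.

Sum-of-metabolite guidance values (DINCH, NMP) weight the summed
component concentrations.  Substances with several alternative sums
(DEHP) get one quotient per sum and the higher one is kept per
individual.  Hazard indices are computed per co-occurrence community
(components mapped to the community holding their metabolites) and
overall; communities with fewer than two weighted members are reported
but flagged as not interpretable as a mixture.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .guidance import (
    GuidanceValue,
    MatchedGuidance,
    convert_units,
    load_database,
    load_molecular_weights,
    match_guidance,
)
from .network import CommunityAssignment

__all__ = [
    "hazard_quotient",
    "sum_metabolite_hq",
    "dehp_hq",
    "compute_hq_matrix",
    "community_hi",
    "HazardResult",
    "exceedance_stats",
    "driver_analysis",
]


def _to_gv_units(concentration, gv: GuidanceValue, creatinine=None, mw=None,
                 biomarker: str = ""):
    return convert_units(concentration, "ug/L", gv.units, creatinine=creatinine,
                         mw=mw, biomarker=biomarker or "/".join(gv.biomarkers))


def hazard_quotient(concentration, gv: GuidanceValue, creatinine=None, mw=None):
    """HQ = concentration (converted to the guidance value's units) / value.

    ``concentration`` is on the raw scale in ug/L (scalar or
    per-individual array); ``creatinine`` (g/L) is required iff the
    guidance value is creatinine-standardized.
    """
    conc = np.asarray(concentration, dtype=float)
    if (conc < 0).any():
        raise ValueError("concentrations must be non-negative")
    converted = _to_gv_units(conc, gv, creatinine=creatinine, mw=mw)
    return converted / gv.value


def sum_metabolite_hq(
    components: pd.DataFrame | dict,
    gv: GuidanceValue,
    creatinine=None,
    mw=None,
):
    """HQ of a sum-of-metabolites guidance value.

    ``components`` maps component biomarker -> per-individual
    concentrations (ug/L).  Components absent from the panel are
    skipped with a coverage warning; the quotient is computed on what
    is available.
    """
    if isinstance(components, dict):
        components = pd.DataFrame(components)
    present = [b for b in gv.biomarkers if b in components.columns]
    absent = [b for b in gv.biomarkers if b not in components.columns]
    if absent:
        warnings.warn(
            f"{gv.label}: components {absent} absent from panel; "
            f"HQ computed on {present}",
            stacklevel=2,
        )
    if not present:
        raise ValueError(f"{gv.label}: no component biomarkers available")
    total = components[present].sum(axis=1).to_numpy(dtype=float)
    return hazard_quotient(total, gv, creatinine=creatinine, mw=mw)


def dehp_hq(
    oh_mehp,
    oxo_mehp,
    cx_mepp,
    db: list[GuidanceValue] | None = None,
):
    """Per-individual DEHP quotient: the higher of the two metabolite sums.

    Two guidance values exist, one for OH-MEHP + oxo-MEHP and one for
    OH-MEHP + cx-MEPP; each individual gets the larger quotient.
    Returns ``(hq, winner)`` where ``winner`` says which sum won per
    individual (ties go to the first sum).
    """
    if db is None:
        db = load_database()
    sums = [gv for gv in db if gv.substance == "DEHP" and gv.is_sum]
    if len(sums) != 2:
        raise ValueError(f"expected two DEHP sum guidance values, found {len(sums)}")
    sums = sorted(sums, key=lambda gv: gv.label)
    oh = np.asarray(oh_mehp, dtype=float)
    oxo = np.asarray(oxo_mehp, dtype=float)
    cx = np.asarray(cx_mepp, dtype=float)
    by_set = {frozenset(gv.biomarkers): gv for gv in sums}
    gv1 = by_set[frozenset({"OH-MEHP", "oxo-MEHP"})]
    gv2 = by_set[frozenset({"OH-MEHP", "cx-MEPP"})]
    hq1 = (oh + oxo) / gv1.value
    hq2 = (oh + cx) / gv2.value
    hq = np.maximum(hq1, hq2)
    winner = np.where(hq1 >= hq2, gv1.label, gv2.label)
    return hq, winner


# ---------------------------------------------------------------------------
# panel-level orchestration
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class HazardResult:
    """Per-individual quotients and community indices.

    ``hq`` is individuals x weighted components; ``community_hi``
    individuals x communities with at least one weighted member;
    ``overall_hi`` the all-component sum.  ``coverage`` counts weighted
    vs unweighted members per community and flags communities whose HI
    is not interpretable as a mixture (fewer than two weighted
    members); ``component_info`` records each component's guidance
    value, type and occupational-fallback flag.
    """

    hq: pd.DataFrame
    community_hi: pd.DataFrame
    overall_hi: pd.Series
    coverage: pd.DataFrame
    component_info: pd.DataFrame
    component_community: dict[str, str | None]


def _component_guidance(
    biomarkers: list[str],
    ages: pd.Series,
    db: list[GuidanceValue],
) -> dict[str, list[tuple]]:
    """Group panel biomarkers into weighted components.

    Returns component name -> list of (guidance, occupational_fallback)
    per unique age where needed.  Sum entries are keyed by substance.
    """
    # collect sum substances present in the db
    components: dict[str, dict] = {}
    sum_substances: dict[str, list[GuidanceValue]] = {}
    for gv in db:
        if gv.is_sum:
            sum_substances.setdefault(gv.substance, []).append(gv)
    covered_by_sum = {b for gvs in sum_substances.values() for gv in gvs for b in gv.biomarkers}

    for b in biomarkers:
        if b in covered_by_sum:
            continue
        # age-dependent entries need a per-age lookup
        per_age = {}
        for age in sorted(ages.unique()):
            m = match_guidance(b, age=float(age), db=db)
            per_age[float(age)] = m
        if all(m is None for m in per_age.values()):
            continue
        components[b] = {"kind": "single", "per_age": per_age, "biomarkers": [b]}

    for substance, gvs in sum_substances.items():
        members = sorted({b for gv in gvs for b in gv.biomarkers})
        if not any(b in biomarkers for b in members):
            continue
        components[substance] = {"kind": "sum", "entries": gvs, "biomarkers": members}
    return components


def compute_hq_matrix(
    concentrations: pd.DataFrame,
    creatinine: pd.Series,
    ages: pd.Series,
    db: list[GuidanceValue] | None = None,
    mw: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, list[str]]]:
    """Hazard quotients for every biomarker with a guidance value.

    ``concentrations`` are raw-scale ug/L (censored/missing cells
    already filled); ``creatinine`` in g/L and ``ages`` in years are
    per-individual.  Returns the HQ matrix (individuals x components),
    a per-component info table (value, units, type, tier, occupational
    fallback) and a mapping component -> member biomarkers.
    """
    if db is None:
        db = load_database()
    if mw is None:
        mw = load_molecular_weights()
    creat = creatinine.to_numpy(dtype=float)
    if (creat <= 0).any():
        raise ValueError("creatinine must be strictly positive")
    components = _component_guidance(list(concentrations.columns), ages, db)

    hq = {}
    info_rows = []
    members_of: dict[str, list[str]] = {}
    age_arr = ages.to_numpy(dtype=float)
    for name, spec in sorted(components.items()):
        if spec["kind"] == "single":
            b = name
            col = concentrations[b].to_numpy(dtype=float)
            out = np.full(len(col), np.nan)
            used: MatchedGuidance | None = None
            for age, m in spec["per_age"].items():
                sel = age_arr == age
                if not sel.any():
                    continue
                if m is None:
                    raise ValueError(f"no guidance value for {b} at age {age:g}")
                used = m
                out[sel] = hazard_quotient(col[sel], m.guidance,
                                           creatinine=creat[sel], mw=mw.get(b))
            hq[name] = out
            members_of[name] = [b]
            # representative entry for the info table (value may vary by age band)
            values = sorted({m.guidance.value for m in spec["per_age"].values() if m})
            info_rows.append((name, used.guidance.substance, values,
                              used.guidance.units, used.guidance.value_type,
                              used.guidance.source_tier, used.occupational_fallback))
        else:  # sum substance
            entries = spec["entries"]
            per_entry = []
            for gv in entries:
                present = [b for b in gv.biomarkers if b in concentrations.columns]
                if not present:
                    continue
                per_entry.append(sum_metabolite_hq(
                    concentrations, gv, creatinine=creat, mw=None))
            if not per_entry:
                continue
            out = np.max(np.vstack(per_entry), axis=0)
            hq[name] = out
            members_of[name] = [b for b in spec["biomarkers"] if b in concentrations.columns]
            gv0 = entries[0]
            info_rows.append((name, gv0.substance, sorted({g.value for g in entries}),
                              gv0.units, gv0.value_type, gv0.source_tier, False))

    hq_df = pd.DataFrame(hq, index=concentrations.index)
    info = pd.DataFrame(
        info_rows,
        columns=["component", "substance", "values", "units", "value_type",
                 "source_tier", "occupational_fallback"],
    ).set_index("component")
    return hq_df, info, members_of


def community_hi(
    hq: pd.DataFrame,
    communities: CommunityAssignment | dict[str, str | None],
    members_of: dict[str, list[str]] | None = None,
    component_info: pd.DataFrame | None = None,
) -> HazardResult:
    """Aggregate quotients into per-community and overall hazard indices.

    A component belongs to the community holding the majority of its
    member biomarkers (ties: the first member's community, with a
    warning).  A community's HI sums the quotients of its weighted
    members; ``overall_hi`` sums every component.  Communities with
    fewer than two weighted members are flagged not interpretable as a
    mixture in the coverage table.
    """
    if isinstance(communities, CommunityAssignment):
        community_of = communities.community_of
    else:
        community_of = dict(communities)
    if members_of is None:
        members_of = {c: [c] for c in hq.columns}

    comp_comm: dict[str, str | None] = {}
    for comp in hq.columns:
        members = members_of.get(comp, [comp])
        labels = [community_of.get(b) for b in members if b in community_of]
        labels = [l for l in labels if l is not None]
        if not labels:
            comp_comm[comp] = None
            continue
        counts = pd.Series(labels).value_counts()
        top = counts[counts == counts.max()].index.tolist()
        if len(top) > 1:
            first = next(community_of.get(b) for b in members
                         if community_of.get(b) in top)
            warnings.warn(
                f"component {comp}: members split evenly across communities "
                f"{sorted(top)}; assigned to {first}",
                stacklevel=2,
            )
            comp_comm[comp] = first
        else:
            comp_comm[comp] = top[0]

    all_labels = sorted({l for l in community_of.values() if l is not None})
    hi_cols = {}
    coverage_rows = []
    for lab in all_labels:
        weighted = [c for c, l in comp_comm.items() if l == lab]
        member_biomarkers = [b for b, l in community_of.items() if l == lab]
        n_weighted_biomarkers = len({b for c in weighted for b in members_of.get(c, [c])
                                     if b in member_biomarkers})
        coverage_rows.append((lab, len(member_biomarkers), len(weighted),
                              n_weighted_biomarkers,
                              len(member_biomarkers) - n_weighted_biomarkers,
                              len(weighted) >= 2))
        if weighted:
            hi_cols[lab] = hq[weighted].sum(axis=1)
    coverage = pd.DataFrame(
        coverage_rows,
        columns=["community", "n_members", "n_weighted_components",
                 "n_weighted_biomarkers", "n_unweighted_biomarkers",
                 "interpretable_as_mixture"],
    ).set_index("community")
    community_hi_df = pd.DataFrame(hi_cols, index=hq.index)
    overall = hq.sum(axis=1).rename("overall_hi")
    if component_info is None:
        component_info = pd.DataFrame(index=hq.columns)
    return HazardResult(
        hq=hq,
        community_hi=community_hi_df,
        overall_hi=overall,
        coverage=coverage,
        component_info=component_info,
        component_community=comp_comm,
    )


def exceedance_stats(values: pd.Series | np.ndarray) -> dict:
    """Exceedance fraction (strictly > 1), geometric mean and percentiles.

    Zeros are excluded from the geometric mean (their count is
    reported).  Raises on an empty vector.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty vector")
    if (x < 0).any():
        raise ValueError("hazard values must be non-negative")
    nz = x[x > 0]
    return {
        "n": int(x.size),
        "exceedance_fraction": float((x > 1).mean()),
        "geometric_mean": float(np.exp(np.mean(np.log(nz)))) if nz.size else np.nan,
        "n_zeros_excluded": int(x.size - nz.size),
        "p50": float(np.percentile(x, 50)),
        "p95": float(np.percentile(x, 95)),
    }


def driver_analysis(
    hq: pd.DataFrame,
    removal_sets: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Which components drive the overall hazard index.

    For each component (or named component set): its share of the mean
    overall HI, and the leave-out ratio mean(HI) / mean(HI without the
    set) — a ratio of 10 means removing the set drops the mean index
    tenfold.  Deterministic; a component with all-zero quotients has
    ratio 1.
    """
    hi = hq.sum(axis=1)
    mean_hi = hi.mean()
    if removal_sets is None:
        removal_sets = {c: [c] for c in hq.columns}
    rows = []
    for name, cols in removal_sets.items():
        mean_part = hq[cols].sum(axis=1).mean()
        rest = mean_hi - mean_part
        share = mean_part / mean_hi if mean_hi > 0 else np.nan
        ratio = mean_hi / rest if rest > 0 else np.inf
        rows.append((name, share, ratio))
    return pd.DataFrame(rows, columns=["component", "mean_share", "removal_ratio"]
                        ).set_index("component")
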