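"""Life-history traits and the person-period table.

Turns longitudinal colony records (one row per detection-year) into the two
layouts all downstream analyses consume:

* a per-female trait table — lifespan, age at first reproduction (AFR),
  lifetime reproductive success (LRS), per-season fecundity — restricted where
  the analysis requires it to females born into the study whose death was
  observed ("complete lives");
* a person-period table with one row per female-year carrying the event
  indicators (reproduced, died) and covariates for discrete-time survival
  models.

AFR and LRS are derived from mother-offspring links (a maternity-assignment
table or the simulator's true pedigree), matching how a genetic pedigree,
rather than direct observation, establishes reproduction in the field.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PedigreeIntegrityError",
    "percentage",
    "compute_traits",
    "build_person_period",
    "cohort_summary",
    "lifespan_by_afr_group",
    "KruskalResult",
]


class PedigreeIntegrityError(ValueError):
    """An offspring refers to a mother absent from the individuals table."""


def percentage(part: float, total: float, decimals: int = 1) -> float:
    """100 * part / total, rounded to the requested precision."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * part / total, decimals)


def _maternity_links(individuals: pd.DataFrame,
                     maternity: pd.DataFrame | dict | None) -> pd.DataFrame:
    """Normalize the maternity source to a frame of offspring/mother/birth_year."""
    ind = individuals.set_index("individual_id", drop=False)
    if maternity is None:
        links = individuals.loc[individuals["mother_id"].notna()
                                & (individuals["mother_id"] != ""),
                                ["individual_id", "mother_id", "birth_year", "sex"]]
        links = links.rename(columns={"individual_id": "offspring_id"})
    else:
        if isinstance(maternity, dict):
            links = pd.DataFrame({"offspring_id": list(maternity),
                                  "mother_id": list(maternity.values())})
        else:
            links = maternity.copy()
            if "accepted" in links.columns:
                links = links.loc[links["accepted"]]
            links = links.rename(columns={"best_candidate_id": "mother_id"})
            links = links[["offspring_id", "mother_id"]]
        links = links.merge(
            ind[["individual_id", "birth_year", "sex"]],
            left_on="offspring_id", right_index=True, how="left")
        if links["birth_year"].isna().any():
            missing = links.loc[links["birth_year"].isna(), "offspring_id"].tolist()
            raise PedigreeIntegrityError(
                f"offspring not present in individuals table: {missing[:5]}")
    unknown = set(links["mother_id"]) - set(ind.index)
    if unknown:
        raise PedigreeIntegrityError(
            f"offspring linked to unknown mother(s): {sorted(unknown)[:5]}")
    return links.reset_index(drop=True)


def compute_traits(individuals: pd.DataFrame, events: pd.DataFrame,
                   maternity: pd.DataFrame | dict | None = None,
                   study_end_year: int | None = None,
                   count_female_only: bool = False,
                   breeding_seasons: str = "all_adult") -> pd.DataFrame:
    """Per-female life-history traits.

    Parameters
    ----------
    individuals, events
        The longitudinal tables (see the simulator's column dictionary).
    maternity
        Mother-offspring links: ``None`` uses the true pedigree column, a dict
        maps offspring id to mother id, a maternity-assignment frame uses its
        accepted rows.
    count_female_only
        Count only female offspring in LRS/AFR (mirrors a study design in
        which only female juveniles are genotyped).
    breeding_seasons
        ``"all_adult"`` counts every adult season (ages 1..max_age) in the
        fecundity denominator; ``"since_first"`` counts seasons from first
        reproduction onward.
    """
    if breeding_seasons not in ("all_adult", "since_first"):
        raise ValueError(f"unknown breeding_seasons mode {breeding_seasons!r}")
    if study_end_year is None:
        study_end_year = int(events["year"].max())
    individuals = individuals.copy()
    individuals["mother_id"] = individuals["mother_id"].replace("", np.nan).infer_objects(copy=False)
    individuals["death_year"] = pd.to_numeric(individuals["death_year"], errors="coerce")

    links = _maternity_links(individuals, maternity)
    if count_female_only:
        links = links.loc[links["sex"] == "F"]
    lrs_count = links.groupby("mother_id").size()
    first_offspring_year = links.groupby("mother_id")["birth_year"].min()

    adult_ids = events.loc[events["age"] >= 1, "individual_id"].unique()
    adults = individuals.set_index("individual_id").loc[adult_ids]

    rows = []
    for iid, row in adults.iterrows():
        dead = not pd.isna(row["death_year"])
        founder = bool(row.get("founder", 0))
        last_year = int(row["death_year"]) if dead else study_end_year
        max_age = last_year - int(row["birth_year"])
        lrs = int(lrs_count.get(iid, 0))
        afr = np.nan
        if lrs > 0:
            afr = float(first_offspring_year[iid] - row["birth_year"])
        complete = dead and not founder
        if breeding_seasons == "all_adult":
            n_seasons = max_age
        else:
            n_seasons = (max_age - int(afr) + 1) if lrs > 0 else 0
        fecundity = np.nan
        if complete:
            fecundity = lrs / n_seasons if n_seasons > 0 else 0.0
        rows.append({
            "individual_id": iid,
            "colony_id": row["colony_id"],
            "birth_year": int(row["birth_year"]),
            "forearm_length_mm": row["forearm_length_mm"],
            "founder": founder,
            "max_age": max_age,
            "age_first_reproduction": afr,
            "lrs": lrs,
            "n_breeding_seasons": n_seasons,
            "fecundity": fecundity,
            "complete_life": complete,
        })
    return pd.DataFrame(rows)


def build_person_period(individuals: pd.DataFrame, events: pd.DataFrame,
                        census: pd.DataFrame, traits: pd.DataFrame | None = None,
                        study_end_year: int | None = None) -> pd.DataFrame:
    """One row per female-year with event indicators and model covariates.

    ``size_centered`` is forearm length minus the analysis cohort's mean (so it
    averages ~0 over individuals).  ``died`` is 1 on the final row of a female
    whose death was observed and 0 everywhere else; right-censored females
    have no ``died=1`` row.  Time-varying reproduction-history covariates
    (``afr_coded``, ``fecundity_to_date``, zero-coded before first
    reproduction) reflect the history *through* the current season; the fixed
    per-individual ``afr_covariate``/``fecundity_covariate`` mirror how a
    completed-life analysis attaches them.

    Raises if any colony-year in the events is missing from the census (no
    imputation).
    """
    if traits is None:
        traits = compute_traits(individuals, events, study_end_year=study_end_year)
    ind = individuals.set_index("individual_id")
    death = pd.to_numeric(ind["death_year"], errors="coerce")

    pp = events.loc[events["age"] >= 1].copy()
    merged = pp.merge(census, on=["colony_id", "year"], how="left")
    if merged["n_adult_females"].isna().any():
        bad = merged.loc[merged["n_adult_females"].isna(),
                         ["colony_id", "year"]].drop_duplicates()
        raise ValueError(f"census missing for colony-years: {bad.values.tolist()[:5]}")
    pp = merged.rename(columns={"n_adult_females": "colony_size"})

    fal = ind.loc[pp["individual_id"], "forearm_length_mm"].to_numpy(dtype=float)
    cohort_mean = float(np.nanmean(
        ind.loc[pp["individual_id"].unique(), "forearm_length_mm"]))
    pp["forearm_length_mm"] = fal
    pp["size_centered"] = fal - cohort_mean
    pp["died"] = (pp["year"].to_numpy()
                  == death.loc[pp["individual_id"]].to_numpy()).astype(int)

    pp = pp.sort_values(["individual_id", "year"], kind="stable").reset_index(drop=True)
    grp = pp.groupby("individual_id", sort=False)
    cum_repro = grp["reproduced"].cumsum()
    ever = (cum_repro > 0).astype(int)
    first_age = pp["age"].where((pp["reproduced"] == 1) & (cum_repro == 1))
    afr_by_ind = first_age.groupby(pp["individual_id"]).transform("max")
    pp["ever_reproduced"] = ever
    pp["afr_coded"] = np.where(ever == 1, afr_by_ind, 0.0)
    pp["fecundity_to_date"] = cum_repro / pp["age"]

    tr = traits.set_index("individual_id")
    pp["afr_covariate"] = tr.loc[pp["individual_id"],
                                 "age_first_reproduction"].fillna(0.0).to_numpy()
    pp["fecundity_covariate"] = tr.loc[pp["individual_id"], "fecundity"].to_numpy()
    pp["complete_life"] = tr.loc[pp["individual_id"], "complete_life"].to_numpy()
    pp.attrs["size_center_mm"] = cohort_mean
    return pp


def cohort_summary(traits: pd.DataFrame, complete_only: bool = True) -> dict:
    """Headline cohort statistics (means/SDs and the never-reproduced share)."""
    if len(traits) == 0:
        raise ValueError("empty trait table")
    t = traits.loc[traits["complete_life"]] if complete_only else traits
    if len(t) == 0:
        raise ValueError("no complete-life females in trait table")
    n_total = len(t)
    n_repro = int((t["lrs"] > 0).sum())
    afr = t["age_first_reproduction"].dropna()
    return {
        "n_total": n_total,
        "n_reproduced": n_repro,
        "pct_never_reproduced": percentage(n_total - n_repro, n_total, 0),
        "mean_fal_mm": round(float(t["forearm_length_mm"].mean()), 1),
        "sd_fal_mm": round(float(t["forearm_length_mm"].std()), 1),
        "mean_afr": round(float(afr.mean()), 1) if len(afr) else None,
        "sd_afr": round(float(afr.std()), 1) if len(afr) > 1 else None,
        "mean_lrs": round(float(t["lrs"].mean()), 2),
        "sd_lrs": round(float(t["lrs"].std()), 2),
        "mean_max_age": round(float(t["max_age"].mean()), 1),
    }


@dataclass
class KruskalResult:
    """Kruskal-Wallis rank test of lifespan across AFR groups."""

    statistic: float
    df: int
    pvalue: float
    group_stats: pd.DataFrame  # group label, n, mean max_age, sd


def lifespan_by_afr_group(traits: pd.DataFrame,
                          late_group_min: int = 3) -> KruskalResult:
    """Kruskal-Wallis test of max age across age-at-first-reproduction groups.

    Groups: first reproduction at age 1, at age 2, and at ``late_group_min``
    or older; complete lives that reproduced at least once.
    """
    t = traits.loc[traits["complete_life"]
                   & traits["age_first_reproduction"].notna()]
    groups = []
    labels = []
    for label, mask in [("afr_1", t["age_first_reproduction"] == 1),
                        ("afr_2", t["age_first_reproduction"] == 2),
                        (f"afr_{late_group_min}plus",
                         t["age_first_reproduction"] >= late_group_min)]:
        vals = t.loc[mask, "max_age"].to_numpy(dtype=float)
        if len(vals) > 0:
            groups.append(vals)
            labels.append(label)
    if len(groups) < 2:
        raise ValueError("need at least two non-empty AFR groups")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        h, p = 0.0, 1.0  # all observations tied: no rank variation
    else:
        h, p = stats.kruskal(*groups)
    stats_rows = [{"group": lab, "n": len(g), "mean_max_age": float(np.mean(g)),
                   "sd_max_age": float(np.std(g, ddof=1)) if len(g) > 1 else np.nan}
                  for lab, g in zip(labels, groups)]
    return KruskalResult(statistic=float(h), df=len(groups) - 1, pvalue=float(p),
                         group_stats=pd.DataFrame(stats_rows))
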