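"""Seeded individual-based simulator for temperate-bat colony life histories.

Emulates the data-generating structure of a long-term mark-recapture study of
female Bechstein's bats (*Myotis bechsteinii*): adult body size (forearm
length, FAL) set once at the end of juvenile growth by the minimum temperature
of a critical mid-summer window and by colony size; annual reproduction
probability increasing with size and age; a discrete annual mortality hazard
increasing with age and with realized reproductive effort (earlier age at
first reproduction, higher per-season fecundity); strict female philopatry, so
a colony census is a near-complete life history. Males are solitary and enter
only as pedigree entries.

The simulator records the generating coefficients in a :class:`TruthRecord`
whose exact dynamic-programming schedules serve as the oracle for
parameter-recovery and demographic-recovery tests downstream.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
import yaml

from .pedigree import GenotypeTable

__all__ = [
    "ConfigError",
    "ReproductionCoefs",
    "HazardCoefs",
    "SimulationConfig",
    "IndividualRecord",
    "Population",
    "TruthRecord",
    "simulate_temperature",
    "simulate_growth",
    "simulate_life",
    "simulate_genotypes",
    "simulate_population",
]


class ConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


def _expit(x: float | np.ndarray) -> float | np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class ReproductionCoefs:
    """Logit-scale coefficients for the annual reproduction probability.

    logit p = intercept + size * (FAL - size_reference)
            + age * age + colony_size * (colony size - colony_size_reference)
    """

    intercept: float = -2.0
    size: float = 0.70
    age: float = 0.20
    colony_size: float = 0.015


@dataclass
class HazardCoefs:
    """Logit-scale coefficients for the annual mortality hazard.

    logit q = intercept + age * age + size * (FAL - size_reference)
            + afr * AFR + fecundity * (offspring so far / age)

    The AFR and fecundity terms are zero-coded until first reproduction.  The
    default ``size`` coefficient is 0: body size influences mortality only
    through the realized reproduction covariates (the mediation structure the
    downstream survival models are designed to detect).
    """

    intercept: float = -2.9
    age: float = 0.22
    size: float = 0.0
    afr: float = -0.55
    fecundity: float = 5.0


@dataclass
class SimulationConfig:
    """Study conditions for one simulated multi-colony, multi-year dataset."""

    n_colonies: int = 4
    colony_size_range: tuple[int, int] = (10, 45)
    n_years: int = 25
    study_start_year: int = 1996
    # critical-window (June 22 - July 16) mean minimum temperature, deg C
    temp_mean: float = 12.0
    temp_sd: float = 1.0
    # adult forearm length model (mm)
    growth_intercept: float = 38.0
    growth_beta_temp: float = 0.35
    growth_beta_colony: float = 0.01
    growth_sd: float = 1.1
    fal_range: tuple[float, float] = (38.0, 47.0)
    # generator centering references
    size_reference_mm: float = 42.7
    colony_size_reference: float = 27.5
    # vital-rate coefficients
    repro_logit_coefs: ReproductionCoefs = field(default_factory=ReproductionCoefs)
    hazard_logit_coefs: HazardCoefs = field(default_factory=HazardCoefs)
    maturity_min_age: int = 1
    event_order: str = "reproduce_then_survive"  # or "survive_then_reproduce"
    offspring_sex_ratio_female: float = 0.518
    # optional catastrophic-mortality year (e.g. a severe winter)
    catastrophic_year: int | None = None
    catastrophic_logit_boost: float = 0.0
    # founders
    founder_max_age: int = 6
    # microsatellite panel
    n_loci: int = 13
    alleles_per_locus: int = 8
    genotyping_error_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        lo, hi = self.colony_size_range
        if not (0 < lo <= hi):
            raise ConfigError(f"colony_size_range must satisfy 0 < low <= high, got {(lo, hi)}")
        if self.n_years < 3:
            raise ConfigError("n_years must be >= 3")
        if self.n_colonies < 1:
            raise ConfigError("n_colonies must be >= 1")
        if self.temp_sd < 0:
            raise ConfigError("temp_sd must be non-negative")
        if self.growth_sd <= 0:
            raise ConfigError("growth_sd must be > 0")
        if not 0.0 <= self.offspring_sex_ratio_female <= 1.0:
            raise ConfigError("offspring_sex_ratio_female must be in [0, 1]")
        if not 0.0 <= self.genotyping_error_rate <= 1.0:
            raise ConfigError("genotyping_error_rate must be in [0, 1]")
        if self.n_loci < 1:
            raise ConfigError("n_loci must be >= 1")
        if self.alleles_per_locus < 1:
            raise ConfigError("alleles_per_locus must be >= 1")
        if self.maturity_min_age < 1:
            raise ConfigError("maturity_min_age must be >= 1")
        if self.event_order not in ("reproduce_then_survive", "survive_then_reproduce"):
            raise ConfigError(f"unknown event_order {self.event_order!r}")
        if not self.fal_range[0] < self.fal_range[1]:
            raise ConfigError("fal_range must be an increasing pair")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["colony_size_range"] = list(self.colony_size_range)
        d["fal_range"] = list(self.fal_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        if "repro_logit_coefs" in d and isinstance(d["repro_logit_coefs"], dict):
            d["repro_logit_coefs"] = ReproductionCoefs(**d["repro_logit_coefs"])
        if "hazard_logit_coefs" in d and isinstance(d["hazard_logit_coefs"], dict):
            d["hazard_logit_coefs"] = HazardCoefs(**d["hazard_logit_coefs"])
        for key in ("colony_size_range", "fal_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError("configuration file must contain a mapping")
        return cls.from_dict(raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @property
    def study_years(self) -> np.ndarray:
        return np.arange(self.study_start_year, self.study_start_year + self.n_years)


# ---------------------------------------------------------------------------
# Individual records
# ---------------------------------------------------------------------------

@dataclass
class IndividualRecord:
    """One individual's full longitudinal history.

    ``alive_by_year``/``reproduced_by_year`` map calendar year -> flag; a dead
    individual is still flagged alive in its death year (it was detected that
    season) but never afterwards.  ``death_year is None`` means right-censored
    at study end.  Male offspring carry pedigree information only (no event
    rows, no forearm measurement).
    """

    individual_id: str
    colony_id: str
    birth_year: int
    sex: str  # 'F' or 'M'
    forearm_length_mm: float
    mother_id: str | None = None
    founder: bool = False
    death_year: int | None = None
    alive_by_year: dict = field(default_factory=dict)
    reproduced_by_year: dict = field(default_factory=dict)

    def age_in(self, year: int) -> int:
        return year - self.birth_year

    @property
    def reproduction_years(self) -> list[int]:
        return sorted(y for y, r in self.reproduced_by_year.items() if r)


@dataclass
class _LifeState:
    """Mutable reproductive history used by the hazard covariates."""

    afr: int | None = None
    n_offspring: int = 0


def _repro_logit(cfg: SimulationConfig, size_c: float, age: int, colony_size: float) -> float:
    r = cfg.repro_logit_coefs
    return (r.intercept + r.size * size_c + r.age * age
            + r.colony_size * (colony_size - cfg.colony_size_reference))


def _hazard_logit(cfg: SimulationConfig, size_c: float, age: int,
                  state: _LifeState, year: int | None = None) -> float:
    h = cfg.hazard_logit_coefs
    x = h.intercept + h.age * age + h.size * size_c
    if state.afr is not None:
        x += h.afr * state.afr + h.fecundity * (state.n_offspring / age)
    if year is not None and year == cfg.catastrophic_year:
        x += cfg.catastrophic_logit_boost
    return x


def _annual_step(cfg: SimulationConfig, size_c: float, age: int, colony_size: float,
                 state: _LifeState, rng: np.random.Generator,
                 year: int | None = None) -> tuple[bool, bool]:
    """One female-year: returns (reproduced, died) and updates ``state``.

    Default ordering is reproduce-then-survive: offspring are censused at the
    maternity roost before overwinter mortality, so a female dying in year y
    can still have weaned a pup that year.
    """
    def try_reproduce() -> bool:
        if age < cfg.maturity_min_age:
            return False
        p = _expit(_repro_logit(cfg, size_c, age, colony_size))
        if rng.random() < p:
            if state.afr is None:
                state.afr = age
            state.n_offspring += 1
            return True
        return False

    if cfg.event_order == "reproduce_then_survive":
        reproduced = try_reproduce()
        died = rng.random() < _expit(_hazard_logit(cfg, size_c, age, state, year))
    else:
        died = rng.random() < _expit(_hazard_logit(cfg, size_c, age, state, year))
        reproduced = False if died else try_reproduce()
    return reproduced, died


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def simulate_temperature(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw the yearly critical-window mean minimum temperature series (i.i.d. normal)."""
    if config.n_years < 1:
        raise ConfigError("n_years must be >= 1")
    if config.temp_sd < 0:
        raise ConfigError("temp_sd must be non-negative")
    return config.temp_mean + config.temp_sd * rng.standard_normal(config.n_years)


def simulate_growth(temp_at_birth, colony_size, config: SimulationConfig,
                    rng: np.random.Generator):
    """Adult forearm length (mm) from birth-year temperature and colony size.

    FAL = intercept + beta_temp * temp + beta_colony * colony_size + N(0, sd),
    clamped to the biological range ``config.fal_range``.  Accepts scalars or
    arrays (broadcast).
    """
    temp = np.asarray(temp_at_birth, dtype=float)
    csize = np.asarray(colony_size, dtype=float)
    if np.any(csize < 1):
        raise ConfigError("colony_size must be >= 1")
    fal = (config.growth_intercept + config.growth_beta_temp * temp
           + config.growth_beta_colony * csize
           + config.growth_sd * rng.standard_normal(np.broadcast(temp, csize).shape))
    out = np.clip(fal, *config.fal_range)
    return float(out) if out.ndim == 0 else out


def simulate_life(record: IndividualRecord, config: SimulationConfig,
                  rng: np.random.Generator, study_end_year: int,
                  colony_size_by_year: Callable[[int], float] | None = None) -> list[int]:
    """Simulate one female's annual loop in place; returns reproduction years.

    The female enters at age 1 (first summer after birth) and each year first
    attempts reproduction, then faces the mortality hazard (ordering per
    ``config.event_order``).  The loop stops at death or at ``study_end_year``
    (right-censoring).  Colony size defaults to the configured reference.
    """
    if not np.isfinite(record.forearm_length_mm):
        raise ValueError("record needs a forearm length before its life can be simulated")
    size_c = record.forearm_length_mm - config.size_reference_mm
    lookup = colony_size_by_year or (lambda _y: config.colony_size_reference)
    state = _LifeState()
    repro_years: list[int] = []
    year = record.birth_year + 1
    while year <= study_end_year:
        age = record.age_in(year)
        record.alive_by_year[year] = True
        reproduced, died = _annual_step(cfg=config, size_c=size_c, age=age,
                                        colony_size=lookup(year), state=state,
                                        rng=rng, year=year)
        record.reproduced_by_year[year] = bool(reproduced)
        if reproduced:
            repro_years.append(year)
        if died:
            record.death_year = year
            break
        year += 1
    return repro_years


# ---------------------------------------------------------------------------
# Whole-population simulation
# ---------------------------------------------------------------------------

@dataclass
class Population:
    """A completed simulated dataset: records, census, genotypes and truth."""

    individuals: list
    config: SimulationConfig
    temperature: pd.Series  # indexed by calendar year
    census: pd.DataFrame  # colony_id, year, n_adult_females
    genotypes: GenotypeTable | None = None
    truth: "TruthRecord | None" = None

    @property
    def study_end_year(self) -> int:
        return int(self.config.study_years[-1])

    def by_id(self) -> dict:
        return {r.individual_id: r for r in self.individuals}

    def individuals_frame(self) -> pd.DataFrame:
        rows = [{
            "individual_id": r.individual_id,
            "colony_id": r.colony_id,
            "birth_year": r.birth_year,
            "sex": r.sex,
            "forearm_length_mm": r.forearm_length_mm,
            "mother_id": r.mother_id if r.mother_id is not None else "",
            "founder": int(r.founder),
            "death_year": r.death_year if r.death_year is not None else "",
        } for r in self.individuals]
        return pd.DataFrame(rows)

    def events_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.individuals:
            for year in sorted(r.alive_by_year):
                rows.append({
                    "individual_id": r.individual_id,
                    "colony_id": r.colony_id,
                    "year": year,
                    "age": r.age_in(year),
                    "alive": 1,
                    "reproduced": int(r.reproduced_by_year.get(year, False)),
                })
        return pd.DataFrame(rows, columns=["individual_id", "colony_id", "year",
                                           "age", "alive", "reproduced"])

    def write_csv(self, outdir) -> dict:
        """Write individuals/events/census (+ genotypes, truth) under ``outdir``."""
        import pathlib

        outdir = pathlib.Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in (("individuals", self.individuals_frame()),
                         ("events", self.events_frame()),
                         ("census", self.census)):
            p = outdir / f"{name}.csv"
            df.to_csv(p, index=False)
            paths[name] = p
        t = pd.DataFrame({"year": self.temperature.index,
                          "temp_c": self.temperature.values})
        p = outdir / "temperature.csv"
        t.to_csv(p, index=False)
        paths["temperature"] = p
        if self.genotypes is not None:
            p = outdir / "genotypes.csv"
            self.genotypes.to_frame().to_csv(p, index=False)
            paths["genotypes"] = p
        if self.truth is not None:
            p = outdir / "truth.json"
            with open(p, "w") as fh:
                json.dump(self.truth.to_dict(), fh, indent=1)
            paths["truth"] = p
        return paths


def simulate_population(config: SimulationConfig,
                        with_genotypes: bool = True) -> Population:
    """Run the full seeded colony simulation.

    Year-by-year loop over colonies: census adult females, let each reproduce
    and face the hazard, enrol newborn female pups as age-1 adults the next
    year.  Founder females seed each colony at the study start with ages drawn
    uniformly from 1..founder_max_age and no pre-study reproductive history.
    Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    years = config.study_years
    temps = simulate_temperature(config, rng)
    temperature = pd.Series(temps, index=years)

    individuals: list[IndividualRecord] = []
    states: dict[str, _LifeState] = {}
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"F{counter:05d}"

    colonies = [f"C{i + 1}" for i in range(config.n_colonies)]
    living: dict[str, list[IndividualRecord]] = {c: [] for c in colonies}

    lo, hi = config.colony_size_range
    for colony in colonies:
        n0 = int(rng.integers(lo, hi + 1))
        for _ in range(n0):
            age0 = int(rng.integers(1, config.founder_max_age + 1))
            temp_birth = config.temp_mean + config.temp_sd * rng.standard_normal()
            fal = simulate_growth(temp_birth, n0, config, rng)
            rec = IndividualRecord(individual_id=new_id(), colony_id=colony,
                                   birth_year=int(years[0]) - age0, sex="F",
                                   forearm_length_mm=float(fal), founder=True)
            individuals.append(rec)
            living[colony].append(rec)
            states[rec.individual_id] = _LifeState()

    census_rows = []
    for t, year in enumerate(years):
        year = int(year)
        newborn_females: dict[str, list[IndividualRecord]] = {c: [] for c in colonies}
        for colony in colonies:
            adults = [r for r in living[colony] if r.age_in(year) >= 1]
            colony_size = len(adults)
            census_rows.append({"colony_id": colony, "year": year,
                                "n_adult_females": colony_size})
            for rec in adults:
                state = states[rec.individual_id]
                size_c = rec.forearm_length_mm - config.size_reference_mm
                rec.alive_by_year[year] = True
                reproduced, died = _annual_step(cfg=config, size_c=size_c,
                                                age=rec.age_in(year),
                                                colony_size=colony_size,
                                                state=state, rng=rng, year=year)
                rec.reproduced_by_year[year] = bool(reproduced)
                if reproduced:
                    sex = "F" if rng.random() < config.offspring_sex_ratio_female else "M"
                    if sex == "F":
                        fal = float(simulate_growth(temps[t], colony_size, config, rng))
                    else:
                        fal = float("nan")
                    pup = IndividualRecord(individual_id=new_id(), colony_id=colony,
                                           birth_year=year, sex=sex,
                                           forearm_length_mm=fal,
                                           mother_id=rec.individual_id)
                    individuals.append(pup)
                    if sex == "F":
                        newborn_females[colony].append(pup)
                        states[pup.individual_id] = _LifeState()
                if died:
                    rec.death_year = year
            living[colony] = [r for r in living[colony] if r.death_year is None]
            living[colony].extend(newborn_females[colony])

    census = pd.DataFrame(census_rows)
    pop = Population(individuals=individuals, config=config,
                     temperature=temperature, census=census)
    if with_genotypes:
        pop.genotypes = simulate_genotypes(pop, config, rng)
    pop.truth = TruthRecord.from_config(config)
    return pop


# ---------------------------------------------------------------------------
# Microsatellite genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(population: Population, config: SimulationConfig,
                       rng: np.random.Generator) -> GenotypeTable:
    """Mendelian multilocus genotypes for every individual in the population.

    Founder allele frequencies per locus are drawn from a flat Dirichlet.
    Offspring inherit one allele from the mother's *true* genotype and one
    paternal allele drawn from the population frequencies (fathers are
    solitary and unsampled).  Each reported allele call is independently
    replaced by a random frequency-weighted allele with probability
    ``genotyping_error_rate``; inheritance always uses the true alleles.
    """
    if config.n_loci < 1:
        raise ConfigError("n_loci must be >= 1")
    k = config.alleles_per_locus
    loci = [f"L{j + 1:02d}" for j in range(config.n_loci)]
    freqs = {loc: rng.dirichlet(np.ones(k)) for loc in loci}

    ordered = sorted(population.individuals, key=lambda r: (r.birth_year, r.individual_id))
    true_geno: dict[str, np.ndarray] = {}  # id -> (n_loci, 2) allele indices
    for rec in ordered:
        g = np.empty((config.n_loci, 2), dtype=np.int64)
        if rec.mother_id is None:
            for j, loc in enumerate(loci):
                g[j] = rng.choice(k, size=2, p=freqs[loc])
        else:
            mom = true_geno[rec.mother_id]
            for j, loc in enumerate(loci):
                g[j, 0] = mom[j, rng.integers(2)]
                g[j, 1] = rng.choice(k, p=freqs[loc])
        true_geno[rec.individual_id] = g

    rows = []
    for rec in ordered:
        g = true_geno[rec.individual_id].copy()
        if config.genotyping_error_rate > 0:
            for j, loc in enumerate(loci):
                for a in range(2):
                    if rng.random() < config.genotyping_error_rate:
                        g[j, a] = rng.choice(k, p=freqs[loc])
        row = {"individual_id": rec.individual_id}
        for j, loc in enumerate(loci):
            pair = sorted(g[j])
            row[f"{loc}_a"] = int(pair[0])
            row[f"{loc}_b"] = int(pair[1])
        rows.append(row)
    table = GenotypeTable(pd.DataFrame(rows), loci=loci)
    table.true_allele_freqs = {loc: freqs[loc].copy() for loc in loci}
    return table


# ---------------------------------------------------------------------------
# Generating truth
# ---------------------------------------------------------------------------

@dataclass
class TruthRecord:
    """The generator's own vital rates, exactly, for recovery tests.

    ``repro_prob_grid``/``baseline_hazard_grid`` are the coefficient-implied
    inverse-logits on a size x age grid (hazard before first reproduction).
    :meth:`exact_schedules` runs an exact dynamic program over the
    reproductive-history state space (age at first reproduction x offspring
    count) and returns the marginal age schedules the simulated cohort
    actually experiences, which feed the true demographic summaries.
    """

    config: SimulationConfig
    size_grid: np.ndarray
    age_grid: np.ndarray
    repro_prob_grid: np.ndarray  # (n_size, n_age)
    baseline_hazard_grid: np.ndarray  # (n_size, n_age)

    @classmethod
    def from_config(cls, config: SimulationConfig,
                    size_grid: np.ndarray | None = None,
                    age_grid: np.ndarray | None = None) -> "TruthRecord":
        if size_grid is None:
            size_grid = np.arange(config.fal_range[0], config.fal_range[1] + 1e-9, 0.5)
        if age_grid is None:
            age_grid = np.arange(1, 22)
        sc = size_grid[:, None] - config.size_reference_mm
        ages = age_grid[None, :]
        repro = _expit(np.vectorize(
            lambda s, a: _repro_logit(config, s, int(a), config.colony_size_reference)
        )(sc, ages))
        base = _expit(np.vectorize(
            lambda s, a: _hazard_logit(config, s, int(a), _LifeState())
        )(sc, ages))
        return cls(config=config, size_grid=np.asarray(size_grid, dtype=float),
                   age_grid=np.asarray(age_grid, dtype=int),
                   repro_prob_grid=repro, baseline_hazard_grid=base)

    # -- exact dynamic program over (afr, offspring-count) states ----------

    def exact_schedules(self, size_mm: float, x_max: int = 21,
                        colony_size: float | None = None) -> dict:
        """Exact marginal age schedules at a given forearm length.

        Returns arrays over ages 1..x_max: ``p_repro`` (state-independent
        annual reproduction probability), ``q_marginal`` (hazard averaged over
        the surviving cohort's reproductive histories), ``l`` (probability of
        being alive at the breeding census of each age, l(1)=1) and the scalar
        ``mean_lifetime_offspring``.  ``colony_size`` sets the local density
        at which reproduction is evaluated (default: the configured
        reference); pass the realized study mean to compare against rates
        fitted on a simulated dataset.
        """
        cfg = self.config
        if colony_size is None:
            colony_size = cfg.colony_size_reference
        size_c = size_mm - cfg.size_reference_mm
        if cfg.event_order != "reproduce_then_survive":
            raise NotImplementedError("exact schedules assume reproduce_then_survive")
        # state: (afr, kids); afr=0 encodes 'never reproduced'
        mass = {(0, 0): 1.0}
        p_repro = np.empty(x_max)
        q_marg = np.empty(x_max)
        l = np.empty(x_max)
        mean_offspring = 0.0
        for a in range(1, x_max + 1):
            alive = sum(mass.values())
            l[a - 1] = alive
            p = float(_expit(_repro_logit(cfg, size_c, a, colony_size)))
            if a < cfg.maturity_min_age:
                p = 0.0
            p_repro[a - 1] = p
            mean_offspring += alive * p
            nxt: dict[tuple[int, int], float] = {}
            dead = 0.0
            for (afr, kids), w in mass.items():
                for reproduced in (False, True):
                    w_branch = w * (p if reproduced else 1.0 - p)
                    if w_branch == 0.0:
                        continue
                    afr2 = afr if not reproduced else (afr or a)
                    kids2 = kids + int(reproduced)
                    st = _LifeState(afr=afr2 or None, n_offspring=kids2)
                    q = float(_expit(_hazard_logit(cfg, size_c, a, st)))
                    dead += w_branch * q
                    key = (afr2, kids2)
                    nxt[key] = nxt.get(key, 0.0) + w_branch * (1.0 - q)
            q_marg[a - 1] = dead / alive if alive > 0 else 0.0
            mass = nxt
        return {"ages": np.arange(1, x_max + 1), "p_repro": p_repro,
                "q_marginal": q_marg, "l": l,
                "mean_lifetime_offspring": mean_offspring}

    def to_dict(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "size_grid": self.size_grid.tolist(),
            "age_grid": self.age_grid.tolist(),
            "repro_prob_grid": np.round(self.repro_prob_grid, 10).tolist(),
            "baseline_hazard_grid": np.round(self.baseline_hazard_grid, 10).tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TruthRecord":
        return cls(config=SimulationConfig.from_dict(d["config"]),
                   size_grid=np.asarray(d["size_grid"], dtype=float),
                   age_grid=np.asarray(d["age_grid"], dtype=int),
                   repro_prob_grid=np.asarray(d["repro_prob_grid"], dtype=float),
                   baseline_hazard_grid=np.asarray(d["baseline_hazard_grid"], dtype=float))
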