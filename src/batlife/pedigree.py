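"""Microsatellite marker diagnostics and likelihood-based maternity assignment.

Implements the single-parent (mother-offspring) assignment rule used with
codominant microsatellite panels: candidate mothers are scored by a LOD — the
log-likelihood ratio of the candidate being the true mother versus an
unrelated female — with the unsampled father marginalized over population
allele frequencies, and an assignment is accepted when the LOD lead (delta)
over the runner-up clears a Monte-Carlo-calibrated strict confidence
threshold, and/or when the pair is fully compatible (0 mismatching loci).

Marker informativeness diagnostics (observed/expected heterozygosity,
polymorphic information content, first-parent non-exclusion probability,
Hardy-Weinberg tests) follow the standard closed forms; the non-exclusion
probability is additionally available by exhaustive enumeration as an
internal cross-check.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenotypeTable",
    "LocusDiagnostics",
    "AssignmentConfig",
    "expected_heterozygosity",
    "polymorphic_information_content",
    "non_exclusion_first_parent",
    "non_exclusion_first_parent_enumeration",
    "locus_diagnostics",
    "mismatch_count",
    "lod_score",
    "LodCalculator",
    "calibrate_delta_threshold",
    "assign_maternity",
]

LOD_IMPOSSIBLE = -math.inf  # sentinel for an excluded (zero-likelihood) pair


# ---------------------------------------------------------------------------
# Genotype container
# ---------------------------------------------------------------------------

class GenotypeTable:
    """Multilocus genotypes in a flat table, two integer allele columns per locus.

    Columns: ``individual_id`` then ``<locus>_a``/``<locus>_b`` per locus.
    Allele frequencies are estimated from the table by counting unless true
    frequencies are attached (``true_allele_freqs``) by a simulator.
    """

    def __init__(self, frame: pd.DataFrame, loci: list[str] | None = None):
        if "individual_id" not in frame.columns:
            raise ValueError("genotype table needs an individual_id column")
        if loci is None:
            loci = sorted({c[:-2] for c in frame.columns if c.endswith("_a")})
        for loc in loci:
            for suffix in ("_a", "_b"):
                if loc + suffix not in frame.columns:
                    raise ValueError(f"missing genotype column {loc + suffix}")
        self._frame = frame.reset_index(drop=True)
        self.loci = list(loci)
        self.true_allele_freqs: dict[str, np.ndarray] | None = None
        self._index = {iid: i for i, iid in enumerate(self._frame["individual_id"])}

    def __len__(self) -> int:
        return len(self._frame)

    @property
    def individual_ids(self) -> list[str]:
        return list(self._frame["individual_id"])

    def to_frame(self) -> pd.DataFrame:
        return self._frame.copy()

    @classmethod
    def read_csv(cls, path) -> "GenotypeTable":
        return cls(pd.read_csv(path))

    def genotype(self, individual_id: str) -> dict[str, tuple[int, int]]:
        i = self._index[individual_id]
        row = self._frame.iloc[i]
        return {loc: (int(row[f"{loc}_a"]), int(row[f"{loc}_b"])) for loc in self.loci}

    def allele_matrix(self) -> np.ndarray:
        """(n_individuals, n_loci, 2) integer allele array."""
        cols = []
        for loc in self.loci:
            cols.append(self._frame[[f"{loc}_a", f"{loc}_b"]].to_numpy(dtype=np.int64))
        return np.stack(cols, axis=1)

    def allele_frequencies(self) -> dict[str, dict[int, float]]:
        """Observed allele frequencies per locus (simple counting)."""
        out = {}
        for loc in self.loci:
            alleles = np.concatenate([self._frame[f"{loc}_a"].to_numpy(),
                                      self._frame[f"{loc}_b"].to_numpy()])
            vals, counts = np.unique(alleles, return_counts=True)
            freqs = counts / counts.sum()
            out[loc] = {int(v): float(f) for v, f in zip(vals, freqs)}
        return out


# ---------------------------------------------------------------------------
# Marker diagnostics
# ---------------------------------------------------------------------------

def expected_heterozygosity(p) -> float:
    """He = 1 - sum p_i^2 for one locus."""
    p = np.asarray(list(p.values()) if isinstance(p, dict) else p, dtype=float)
    return float(1.0 - np.sum(p ** 2))


def polymorphic_information_content(p) -> float:
    """PIC = 1 - sum p_i^2 - sum_{i<j} 2 p_i^2 p_j^2."""
    p = np.asarray(list(p.values()) if isinstance(p, dict) else p, dtype=float)
    a2 = np.sum(p ** 2)
    a4 = np.sum(p ** 4)
    return float(1.0 - a2 - (a2 ** 2 - a4))


def non_exclusion_first_parent(p) -> float:
    """Closed-form first-parent non-exclusion probability for one locus.

    Complement of the average exclusion probability for the first parent
    (no known partner): E1 = 1 - 4 a2 + 2 a2^2 + 4 a3 - 3 a4 with
    a_n = sum p_i^n; NE1 = 1 - E1.
    """
    p = np.asarray(list(p.values()) if isinstance(p, dict) else p, dtype=float)
    a2 = np.sum(p ** 2)
    a3 = np.sum(p ** 3)
    a4 = np.sum(p ** 4)
    return float(4 * a2 - 2 * a2 ** 2 - 4 * a3 + 3 * a4)


def non_exclusion_first_parent_enumeration(p) -> float:
    """NE1 by exhaustive enumeration over ordered HWE genotype pairs.

    Probability that a random unrelated candidate shares at least one allele
    with a random offspring, both drawn under Hardy-Weinberg equilibrium.
    """
    p = np.asarray(list(p.values()) if isinstance(p, dict) else p, dtype=float)
    k = len(p)
    total = 0.0
    for o1 in range(k):
        for o2 in range(k):
            po = p[o1] * p[o2]
            for c1 in range(k):
                for c2 in range(k):
                    if c1 in (o1, o2) or c2 in (o1, o2):
                        total += po * p[c1] * p[c2]
    return float(total)


@dataclass
class LocusDiagnostics:
    """Per-locus marker diagnostics plus the combined non-exclusion probability."""

    per_locus: pd.DataFrame  # locus, n, Ho, He, PIC, NE1, hwe_chi2, hwe_df, hwe_p
    combined_ne1: float


def locus_diagnostics(genotypes: GenotypeTable) -> LocusDiagnostics:
    """Compute Ho, He, PIC, NE1 and an HWE chi-square test for every locus."""
    frame = genotypes.to_frame()
    freqs = genotypes.allele_frequencies()
    rows = []
    combined = 1.0
    for loc in genotypes.loci:
        p = freqs[loc]
        if len(p) < 2:
            raise ValueError(f"locus {loc} is monomorphic; He/PIC undefined")
        a = frame[f"{loc}_a"].to_numpy()
        b = frame[f"{loc}_b"].to_numpy()
        n = len(a)
        ho = float(np.mean(a != b))
        he = expected_heterozygosity(p)
        pic = polymorphic_information_content(p)
        ne1 = non_exclusion_first_parent(p)
        combined *= ne1
        # HWE chi-square on genotype counts
        alleles = sorted(p)
        pv = np.array([p[x] for x in alleles])
        idx = {x: i for i, x in enumerate(alleles)}
        k = len(alleles)
        obs = np.zeros((k, k))
        for ai, bi in zip(a, b):
            i, j = sorted((idx[ai], idx[bi]))
            obs[i, j] += 1
        exp = np.zeros((k, k))
        for i in range(k):
            exp[i, i] = n * pv[i] ** 2
            for j in range(i + 1, k):
                exp[i, j] = n * 2 * pv[i] * pv[j]
        mask = exp > 0
        chi2 = float(np.sum((obs[mask] - exp[mask]) ** 2 / exp[mask]))
        df = int(mask.sum() - k)
        hwe_p = float(stats.chi2.sf(chi2, df)) if df > 0 else float("nan")
        rows.append({"locus": loc, "n": n, "Ho": ho, "He": he, "PIC": pic,
                     "NE1": ne1, "hwe_chi2": chi2, "hwe_df": df, "hwe_p": hwe_p})
    return LocusDiagnostics(per_locus=pd.DataFrame(rows), combined_ne1=float(combined))


# ---------------------------------------------------------------------------
# Mismatches and LOD scores
# ---------------------------------------------------------------------------

def mismatch_count(offspring_genotype: dict, candidate_genotype: dict) -> int:
    """Number of loci at which the candidate shares no allele with the offspring."""
    if set(offspring_genotype) != set(candidate_genotype):
        raise ValueError("offspring and candidate must be typed at the same loci")
    n = 0
    for loc, (o1, o2) in offspring_genotype.items():
        c1, c2 = candidate_genotype[loc]
        if o1 not in (c1, c2) and o2 not in (c1, c2):
            n += 1
    return n


class LodCalculator:
    """Precomputed per-locus likelihood-ratio tables for mother-offspring LODs.

    For each locus, enumerates ordered true genotypes of mother and offspring
    under HWE, the Mendelian transmission with the paternal allele drawn from
    population frequencies, and an observation model in which each reported
    allele is independently mis-scored (replaced by a frequency-weighted
    random allele) with probability ``error_rate``.  The joint probability of
    the observed unordered genotype pair under "candidate is the mother"
    divided by the same under "candidate unrelated" gives the per-locus
    likelihood ratio; the LOD is the sum of the log ratios over loci.
    """

    def __init__(self, allele_freqs: dict[str, dict[int, float]], error_rate: float = 0.0):
        if not 0.0 <= error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")
        self.error_rate = float(error_rate)
        self.loci = list(allele_freqs)
        self._alleles: dict[str, list[int]] = {}
        self._geno_index: dict[str, dict[tuple[int, int], int]] = {}
        self._log_lr: dict[str, np.ndarray] = {}
        self._freqs: dict[str, np.ndarray] = {}
        for loc, fr in allele_freqs.items():
            self._build_locus(loc, fr)

    def _build_locus(self, loc: str, fr: dict[int, float]) -> None:
        alleles = sorted(fr)
        p = np.array([fr[a] for a in alleles], dtype=float)
        if np.any(p <= 0):
            floor = p[p > 0].min() if np.any(p > 0) else 1.0
            warnings.warn(f"locus {loc}: zero-frequency alleles floored at {floor:g}")
            p = np.maximum(p, floor)
        p = p / p.sum()
        k = len(alleles)
        eps = self.error_rate
        # allele observation model: e[a, b] = P(report b | true a)
        e = (1 - eps) * np.eye(k) + eps * p[None, :]
        # ordered-genotype spaces, index g = a1 * k + a2
        prior = np.kron(p, p)  # HWE ordered prior
        E_ord = np.kron(e, e)  # P(ordered report | ordered truth)
        # collapse reported ordered pairs to unordered genotype classes
        unordered = [(alleles[i], alleles[j]) for i in range(k) for j in range(i, k)]
        uidx = {g: u for u, g in enumerate(unordered)}
        U = np.zeros((k * k, len(unordered)))
        for b1 in range(k):
            for b2 in range(k):
                key = (alleles[min(b1, b2)], alleles[max(b1, b2)])
                U[b1 * k + b2, uidx[key]] = 1.0
        E_u = E_ord @ U  # P(unordered report | ordered truth)
        # Mendelian transmission, ordered: offspring = (maternal, paternal)
        T = np.zeros((k * k, k * k))
        for m1 in range(k):
            for m2 in range(k):
                gm = m1 * k + m2
                for o1 in range(k):
                    w = 0.5 * ((o1 == m1) + (o1 == m2))
                    if w == 0.0:
                        continue
                    T[gm, o1 * k:(o1 + 1) * k] += w * p
        # joint prob of (offspring report, mother report) under maternity
        weighted = prior[:, None] * E_u  # (gm, u_m)
        num = E_u.T @ (T.T @ weighted)  # (u_o, u_m)
        marg = prior @ E_u  # P(unordered report) under HWE
        den = np.outer(marg, marg)
        with np.errstate(divide="ignore"):
            self._log_lr[loc] = np.where(num > 0, np.log(num / den), -np.inf)
        self._alleles[loc] = alleles
        self._geno_index[loc] = uidx
        self._freqs[loc] = p

    def _index_of(self, loc: str, genotype: tuple[int, int]) -> int:
        a, b = sorted(genotype)
        uidx = self._geno_index[loc]
        key = (a, b)
        if key not in uidx:
            raise KeyError(f"genotype {genotype} at locus {loc} contains an allele "
                           "absent from the frequency table")
        return uidx[key]

    def lod(self, offspring_genotype: dict, candidate_genotype: dict) -> float:
        total = 0.0
        for loc in self.loci:
            lr = self._log_lr[loc][self._index_of(loc, offspring_genotype[loc]),
                                   self._index_of(loc, candidate_genotype[loc])]
            if lr == -np.inf:
                return LOD_IMPOSSIBLE
            total += lr
        return float(total)


def lod_score(offspring_genotype: dict, candidate_genotype: dict,
              allele_freqs: dict[str, dict[int, float]], error_rate: float = 0.0) -> float:
    """LOD of the candidate being the offspring's mother vs an unrelated female."""
    return LodCalculator(allele_freqs, error_rate).lod(offspring_genotype,
                                                       candidate_genotype)


# ---------------------------------------------------------------------------
# Assignment with Monte-Carlo delta calibration
# ---------------------------------------------------------------------------

@dataclass
class AssignmentConfig:
    """Settings for maternity assignment and its confidence calibration."""

    error_rate: float = 0.01
    confidence: float = 0.95
    n_simulations: int = 10_000
    n_candidates: int = 20  # typical candidate-mother pool per colony-year
    prop_mother_sampled: float = 1.0  # philopatric females: mother in pool if alive
    seed: int = 1234


def _pair_index(i: np.ndarray, j: np.ndarray, k: int) -> np.ndarray:
    """Unordered-genotype index of allele-position pair (i, j) among k alleles."""
    lo = np.minimum(i, j)
    hi = np.maximum(i, j)
    return lo * k - lo * (lo - 1) // 2 + (hi - lo)


def calibrate_delta_threshold(allele_freqs: dict[str, dict[int, float]],
                              config: AssignmentConfig) -> float:
    """Strict-confidence delta threshold by Monte-Carlo simulation.

    Simulates offspring with a known mother drawn from the supplied allele
    frequencies, scores a candidate pool containing the (error-perturbed)
    true mother plus unrelated females, and finds the smallest delta
    (best-minus-second LOD) such that assignments clearing it are correct in
    at least the requested fraction of simulations.
    """
    rng = np.random.default_rng(config.seed)
    calc = LodCalculator(allele_freqs, config.error_rate)
    n_sim = config.n_simulations
    n_cand = config.n_candidates
    eps = calc.error_rate

    lods = np.zeros((n_sim, n_cand))
    mother_in = rng.random(n_sim) < config.prop_mother_sampled
    for loc in calc.loci:
        p = calc._freqs[loc]
        k = len(p)

        def draw(shape):
            return rng.choice(k, size=shape, p=p)

        def observe(true):
            noisy = draw(true.shape)
            mask = rng.random(true.shape) < eps
            return np.where(mask, noisy, true)

        mother_true = draw((n_sim, 2))
        maternal = np.take_along_axis(
            mother_true, rng.integers(2, size=(n_sim, 1)), axis=1)[:, 0]
        off_obs = observe(np.stack([maternal, draw(n_sim)], axis=1))
        cand_true = draw((n_sim, n_cand, 2))
        # slot 0 holds the true mother where she is in the candidate pool
        cand_true[mother_in, 0, :] = mother_true[mother_in]
        cand_obs = observe(cand_true)
        u_off = _pair_index(off_obs[:, 0], off_obs[:, 1], k)
        u_cand = _pair_index(cand_obs[:, :, 0], cand_obs[:, :, 1], k)
        lods += calc._log_lr[loc][u_off[:, None], u_cand]

    order = np.argsort(lods, axis=1)[:, ::-1]
    best = order[:, 0]
    best_lod = np.take_along_axis(lods, order[:, :1], axis=1)[:, 0]
    if n_cand > 1:
        second = np.take_along_axis(lods, order[:, 1:2], axis=1)[:, 0]
        deltas = np.where(np.isfinite(second), best_lod - second, best_lod)
    else:
        deltas = best_lod.copy()
    keep = np.isfinite(best_lod)
    deltas = deltas[keep]
    corrects = (best == 0)[keep] & mother_in[keep]
    order = np.argsort(deltas)[::-1]
    n_correct = np.cumsum(corrects[order])
    n_total = np.arange(1, len(order) + 1)
    precision = n_correct / n_total
    ok = precision >= config.confidence
    if not ok.any():
        return float("inf")
    last = np.max(np.nonzero(ok)[0])
    if last == len(order) - 1:
        return 0.0
    return float(deltas[order[last]])


def assign_maternity(offspring_ids: list[str],
                     candidate_sets: dict[str, list[str]],
                     genotypes: GenotypeTable,
                     config: AssignmentConfig | None = None,
                     allele_freqs: dict[str, dict[int, float]] | None = None,
                     delta_threshold: float | None = None) -> pd.DataFrame:
    """Assign each offspring to its most likely candidate mother.

    ``candidate_sets`` maps each offspring to the females detected alive in
    its colony and birth year.  An assignment is accepted when the LOD lead
    over the runner-up reaches the strict-confidence threshold (calibrated by
    simulation unless supplied), and/or when the best candidate has zero
    mismatching loci.  Returns one row per offspring.
    """
    config = config or AssignmentConfig()
    if allele_freqs is None:
        allele_freqs = genotypes.allele_frequencies()
    calc = LodCalculator(allele_freqs, config.error_rate)
    if delta_threshold is None:
        delta_threshold = calibrate_delta_threshold(allele_freqs, config)

    rows = []
    for off in offspring_ids:
        cands = candidate_sets.get(off, [])
        if not cands:
            raise ValueError(f"empty candidate set for offspring {off}")
        g_off = genotypes.genotype(off)
        lods = []
        mism = []
        for cand in cands:
            g_c = genotypes.genotype(cand)
            lods.append(calc.lod(g_off, g_c))
            mism.append(mismatch_count(g_off, g_c))
        lods = np.asarray(lods)
        order = np.argsort(lods)[::-1]
        best = int(order[0])
        delta = float(lods[best] - lods[order[1]]) if len(cands) > 1 else float("inf")
        strict = bool(np.isfinite(lods[best]) and delta >= delta_threshold)
        accepted = strict or mism[best] == 0
        rows.append({
            "offspring_id": off,
            "best_candidate_id": cands[best],
            "mismatch_count": int(mism[best]),
            "lod": float(lods[best]),
            "delta": delta,
            "confidence": "95% strict" if strict else "unassigned",
            "accepted": bool(accepted),
        })
    result = pd.DataFrame(rows)
    result.attrs["delta_threshold"] = float(delta_threshold)
    return result
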