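"""Cohort-level statistics on copy-number genotype tables.

Implements the evaluation statistics used for population-scale copy-number
genotypes: Hardy-Weinberg equilibrium per subgroup, trio-concordance F-1
error, a multi-state generalization of F_ST, multiallelic linkage
disequilibrium (mLD), relative paralog divergence (RPD), copy-number mean
absolute pairwise error, and subgroup saturation/recapture curves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2

log = logging.getLogger(__name__)

__all__ = [
    "PopTable",
    "StatResult",
    "cn_mae",
    "f_statistic",
    "hwe_exact_test",
    "hwe_test",
    "multiallelic_ld",
    "rpd",
    "saturation_curve",
    "trio_concordance",
]


@dataclass
class StatResult:
    statistic: float
    p_value: float | None
    n: int
    method: str

    def __post_init__(self) -> None:
        if self.p_value is not None and not (0.0 <= self.p_value <= 1.0 + 1e-12):
            raise ValueError(f"p-value out of range: {self.p_value}")


@dataclass
class PopTable:
    """Samples x subgroups copy-number table with cohort metadata."""

    cn: pd.DataFrame  # index = samples, columns = subgroup ids, integer CN
    populations: pd.Series | None = None  # sample -> population label
    trios: pd.DataFrame | None = None  # columns: child, father, mother

    def __post_init__(self) -> None:
        if (self.cn.values < 0).any():
            raise ValueError("copy numbers must be >= 0")
        if self.trios is not None:
            present = set(self.cn.index)
            missing = set(self.trios.values.ravel()) - present
            if missing:
                log.warning("trio members absent from table: %s", sorted(missing)[:5])


# ---------------------------------------------------------------------------
# Hardy-Weinberg equilibrium


def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact Hardy-Weinberg test, conditioning on allele counts.

    Sums probabilities of all heterozygote counts no more likely than the
    observed one, under the hypergeometric sampling distribution of
    genotypes given allele counts.
    """
    n = n_aa + n_ab + n_bb
    na = 2 * n_aa + n_ab  # minor/major orientation does not matter
    nb = 2 * n - na

    def logp(het: int) -> float:
        hom_a = (na - het) // 2
        hom_b = (nb - het) // 2
        return (
            gammaln(n + 1)
            - gammaln(hom_a + 1)
            - gammaln(het + 1)
            - gammaln(hom_b + 1)
            + het * np.log(2)
            + gammaln(na + 1)
            + gammaln(nb + 1)
            - gammaln(2 * n + 1)
        )

    parity = na % 2
    hets = range(parity, min(na, nb) + 1, 2)
    logs = np.array([logp(h) for h in hets])
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    obs = list(hets).index(n_ab)
    return float(probs[probs <= probs[obs] + 1e-12].sum())


def hwe_test(cns: Sequence[int], eligibility: float = 0.95) -> StatResult | None:
    """HWE goodness-of-fit for a subgroup, treating CN as a diploid genotype.

    Only subgroups with CN in {0,1,2} in >= ``eligibility`` of samples are
    testable (returns None otherwise, logged); samples above CN 2 are
    excluded.  The allele frequency is p̂ = mean(CN)/2 and observed counts
    are compared to (q̂², 2p̂q̂, p̂²)·n with a chi-squared test (df=1), or an
    exact test when any expected cell drops below 5.  Monomorphic
    subgroups give p = 1 by convention.
    """
    cns = np.asarray(cns, dtype=np.int64)
    ok = (cns >= 0) & (cns <= 2)
    if len(cns) == 0 or ok.mean() < eligibility:
        log.info("subgroup excluded from HWE: %.1f%% of samples outside CN 0-2",
                 100 * (1 - ok.mean() if len(cns) else 1))
        return None
    g = cns[ok]
    n = g.size
    obs = np.array([(g == 0).sum(), (g == 1).sum(), (g == 2).sum()], dtype=float)
    p_hat = g.mean() / 2.0
    q_hat = 1.0 - p_hat
    if p_hat in (0.0, 1.0):
        return StatResult(0.0, 1.0, n, "monomorphic")
    exp = np.array([q_hat**2, 2 * p_hat * q_hat, p_hat**2]) * n
    if (exp < 5).any():
        p = hwe_exact_test(int(obs[0]), int(obs[1]), int(obs[2]))
        return StatResult(float("nan"), p, n, "exact")
    stat = float(((obs - exp) ** 2 / exp).sum())
    return StatResult(stat, float(chi2.sf(stat, df=1)), n, "chi2")


# ---------------------------------------------------------------------------
# trio concordance


def trio_concordance(
    table: PopTable,
    single_hap_max: Mapping[str, int] | int = 1,
) -> tuple[float, pd.DataFrame]:
    """Mendelian-consistency F-1 error of trio genotypes.

    For each subgroup and trio: copies in the child beyond the parents'
    total are false-positive units, FP = max(0, c − f − m).  A parent with
    more copies than twice what one haplotype can carry must transmit at
    least obligate = max(0, CN_p − single_hap_max); shortfalls in the child
    are false negatives, FN = max(0, Σ obligate − c).  The F-1 error is
    (FP+FN) / (FP+FN+2·concordant units), aggregated over trios.  Trios
    with a missing member are skipped.
    """
    if table.trios is None or table.trios.empty:
        raise ValueError("table has no trios")
    cn = table.cn
    rows = []
    for sid in cn.columns:
        shm = single_hap_max[sid] if isinstance(single_hap_max, Mapping) else single_hap_max
        fp = fn = conc = 0
        n_trios = 0
        for _, trio in table.trios.iterrows():
            child, father, mother = trio["child"], trio["father"], trio["mother"]
            if not all(s in cn.index for s in (child, father, mother)):
                continue
            c = int(cn.at[child, sid])
            f = int(cn.at[father, sid])
            m = int(cn.at[mother, sid])
            t_fp = max(0, c - f - m)
            obligate = max(0, f - shm) + max(0, m - shm)
            t_fn = max(0, obligate - c)
            fp += t_fp
            fn += t_fn
            conc += c - t_fp
            n_trios += 1
        denom = fp + fn + 2 * conc
        err = (fp + fn) / denom if denom else 0.0
        rows.append({"subgroup": sid, "FP": fp, "FN": fn, "concordant": conc,
                     "f1_error": err, "n_trios": n_trios})
    per_sub = pd.DataFrame(rows).set_index("subgroup")
    tot_fp, tot_fn, tot_c = per_sub["FP"].sum(), per_sub["FN"].sum(), per_sub["concordant"].sum()
    denom = tot_fp + tot_fn + 2 * tot_c
    overall = float((tot_fp + tot_fn) / denom) if denom else 0.0
    return overall, per_sub


# ---------------------------------------------------------------------------
# population differentiation


def _gene_diversity(states: Sequence) -> float:
    _, counts = np.unique(np.asarray(states), return_counts=True)
    f = counts / counts.sum()
    return float(1.0 - (f**2).sum())


def f_statistic(
    states: Sequence,
    populations: Sequence,
    min_pop_size: int = 2,
) -> StatResult:
    """Multi-state generalization of F_ST over copy-number states.

    Each distinct CN state is an unordered allele; F = (H_T − H̄_S)/H_T with
    H = 1 − Σ f², H̄_S the population-size-weighted mean within-population
    diversity and H_T the pooled diversity.  F = 0 when H_T = 0.
    Populations below ``min_pop_size`` samples are excluded (logged).
    """
    states = np.asarray(states)
    populations = np.asarray(populations)
    keep = np.ones(states.size, dtype=bool)
    for pop in np.unique(populations):
        m = populations == pop
        if m.sum() < min_pop_size:
            log.info("population %s has < %d samples; excluded", pop, min_pop_size)
            keep &= ~m
    states, populations = states[keep], populations[keep]
    pops = np.unique(populations)
    if pops.size < 2:
        raise ValueError("need >= 2 populations after exclusion")
    h_t = _gene_diversity(states)
    if h_t == 0:
        return StatResult(0.0, None, states.size, "F-statistic")
    sizes = np.array([(populations == p).sum() for p in pops], dtype=float)
    h_s = np.array([_gene_diversity(states[populations == p]) for p in pops])
    h_s_bar = float((sizes * h_s).sum() / sizes.sum())
    return StatResult((h_t - h_s_bar) / h_t, None, states.size, "F-statistic")


# ---------------------------------------------------------------------------
# multiallelic linkage disequilibrium


def multiallelic_ld(hap_counts: Mapping[tuple, float]) -> float | None:
    """Frequency-weighted multiallelic |D′| between two loci.

    ``hap_counts`` maps (state_at_A, state_at_B) -> haplotype count.
    D_ij = x_ij − p_i q_j; each D is normalized by its frequency-bound
    maximum and combined as mLD = Σ_ij p_i q_j |D′_ij|, which lies in
    [0, 1].  A monomorphic locus leaves mLD undefined (None).
    """
    total = float(sum(hap_counts.values()))
    if total <= 0:
        return None
    a_states = sorted({a for a, _ in hap_counts})
    b_states = sorted({b for _, b in hap_counts})
    if len(a_states) < 2 or len(b_states) < 2:
        return None
    p = {a: sum(v for (x, _), v in hap_counts.items() if x == a) / total for a in a_states}
    q = {b: sum(v for (_, y), v in hap_counts.items() if y == b) / total for b in b_states}
    mld = 0.0
    for a in a_states:
        for b in b_states:
            x = hap_counts.get((a, b), 0.0) / total
            d = x - p[a] * q[b]
            if d >= 0:
                dmax = min(p[a] * (1 - q[b]), (1 - p[a]) * q[b])
            else:
                dmax = min(p[a] * q[b], (1 - p[a]) * (1 - q[b]))
            dprime = abs(d) / dmax if dmax > 0 else 0.0
            mld += p[a] * q[b] * dprime
    return float(mld)


# ---------------------------------------------------------------------------
# divergence and copy-number variability


def rpd(
    paralog_divergences: Sequence[float],
    ortholog_divergences: Sequence[float],
) -> float | None:
    """Relative paralog divergence: mean paralog / mean ortholog divergence.

    Inputs are per-pair substitution rates on non-repetitive sequence.
    Returns None when no paralog pairs exist or the ortholog mean is zero.
    """
    par = np.asarray(paralog_divergences, dtype=float)
    ort = np.asarray(ortholog_divergences, dtype=float)
    if par.size == 0:
        return None
    if ort.size == 0 or ort.mean() == 0:
        return None
    return float(par.mean() / ort.mean())


def cn_mae(cns: Sequence[float]) -> float:
    """Mean absolute copy-number difference over unordered sample pairs."""
    cns = np.asarray(cns, dtype=float)
    if cns.size < 2:
        raise ValueError("need >= 2 samples")
    diffs = [abs(a - b) for a, b in combinations(cns, 2)]
    return float(np.mean(diffs))


# ---------------------------------------------------------------------------
# saturation


def saturation_curve(
    subgroup_sets: Sequence[Iterable],
    order: Sequence[int] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative subgroup discovery and per-new-genome unseen rate.

    ``subgroup_sets[i]`` is the set of subgroups observed in genome i;
    ``order`` optionally reorders genomes (e.g. one population first).
    Returns (curve, unseen): curve[n-1] is the fraction of all subgroups
    seen in the first n genomes; unseen[n-1] is the mean fraction of a
    not-yet-included genome's subgroups absent from the first n (defined
    for n < N).  Empty sets are skipped.
    """
    sets = [set(s) for s in subgroup_sets]
    if order is not None:
        sets = [sets[i] for i in order]
    sets = [s for s in sets if s]
    if not sets:
        raise ValueError("all subgroup sets are empty")
    universe = set().union(*sets)
    curve = np.zeros(len(sets))
    unseen = np.zeros(max(0, len(sets) - 1))
    seen: set = set()
    for n, s in enumerate(sets, start=1):
        seen |= s
        curve[n - 1] = len(seen) / len(universe)
        if n < len(sets):
            rates = [len(t - seen) / len(t) for t in sets[n:]]
            unseen[n - 1] = float(np.mean(rates))
    return curve, unseen
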