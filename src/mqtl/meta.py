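"""Meta-QTL detection: mixture clustering of projected QTL per chromosome.

Model
-----
QTL positions reported by independent studies are treated as noisy
observations of a small number of underlying loci.  On one chromosome the
observed positions x_1..x_n follow the mixture

    x_i ~ sum_k p_k * Normal(mu_k, s_i^2)

where the per-observation standard deviation s_i is known, derived from each
QTL's 95% confidence interval (s_i = CI95 / (2 * 1.96)); only the component
means mu_k and mixing weights p_k are estimated (nu = 2K - 1 free
parameters).  EM fits the model for K = 1..Kmax and the number of "real"
loci is chosen by vote among five information criteria (AIC, AICc, AIC3,
BIC, AWE).  Each QTL is then hard-assigned to its most probable component
and every component becomes a meta-QTL whose position is the
inverse-variance weighted mean of its members, with a 95% CI from the
combined precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import logsumexp

from .errors import MQTLError
from .io import GeneticMap, natural_chrom_key
from .projection import ProjectedQTL

Z95 = 1.96  # two-sided 95% normal quantile, at the precision used throughout

TISSUE_PREFIX = {"leaf": "LIR", "stem": "SIR", "kernel": "KIR"}

CRITERIA = ("AIC", "AICc", "AIC3", "BIC", "AWE")


def qtl_sd(ci95_width: float) -> float:
    """Standard deviation implied by a 95% CI width: w / (2 * 1.96)."""
    if ci95_width <= 0 or not math.isfinite(ci95_width):
        raise MQTLError(f"CI width must be positive, got {ci95_width}")
    return ci95_width / (2.0 * 1.96)


@dataclass
class MixtureFit:
    """EM fit of a K-component normal mixture with known observation SDs."""

    K: int
    means: np.ndarray
    weights: np.ndarray
    loglik: float
    responsibilities: np.ndarray  # (n, K)
    n_params: int
    converged: bool
    n_iter: int
    loglik_trace: list[float]
    positions: np.ndarray
    sds: np.ndarray


@dataclass
class ModelSelection:
    """Per-K criterion values, each criterion's vote, and the chosen K."""

    table: dict[str, dict[int, float]]  # criterion -> {K: value}
    votes: dict[str, int]  # criterion -> K
    chosen_K: int
    strategy: str


@dataclass
class MQTL:
    """A consensus QTL: position, 95% CI, members, flanks, physical span."""

    mqtl_id: str
    tissue_class: str
    chromosome: str
    position: float
    ci95_start: float
    ci95_end: float
    sd: float
    members: list[tuple[str, float]] = field(default_factory=list)
    flank_left: str | None = None
    flank_right: str | None = None
    phys_start_bp: float | None = None
    phys_end_bp: float | None = None
    phys_start_open: bool = False
    phys_end_open: bool = False
    reported_ci_width: float | None = None

    @property
    def ci_width(self) -> float:
        """CI width used for coverage sums (reported width when curated)."""
        if self.reported_ci_width is not None:
            return self.reported_ci_width
        return self.ci95_end - self.ci95_start


def _log_density(x: np.ndarray, s2: np.ndarray, means: np.ndarray) -> np.ndarray:
    """(n, K) matrix of log Normal(x_i; mu_k, s_i^2)."""
    diff = x[:, None] - means[None, :]
    return -0.5 * (np.log(2.0 * np.pi * s2)[:, None] + diff ** 2 / s2[:, None])


def _weighted_mean(x: np.ndarray, w: np.ndarray) -> float:
    return float(np.sum(w * x) / np.sum(w))


def _init_means(x: np.ndarray, K: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++-style seeding on the observed positions."""
    means = [x[rng.integers(len(x))]]
    while len(means) < K:
        d2 = np.min((x[:, None] - np.array(means)[None, :]) ** 2, axis=1)
        total = d2.sum()
        if total <= 0:
            means.append(x[rng.integers(len(x))])
            continue
        means.append(x[rng.choice(len(x), p=d2 / total)])
    return np.array(means, dtype=float)


def fit_mixture(positions: Sequence[float], sds: Sequence[float], K: int,
                seed: int = 0, n_restarts: int = 10, max_iter: int = 500,
                tol: float = 1e-8) -> MixtureFit:
    """Fit the K-component mixture by EM with fixed observation variances.

    K = 1 is solved in closed form (inverse-variance weighted mean).  For
    K > 1, EM is restarted ``n_restarts`` times from k-means++-style initial
    means and the best log-likelihood is kept; the whole procedure is
    deterministic under ``seed``.
    """
    x = np.asarray(positions, dtype=float)
    s = np.asarray(sds, dtype=float)
    n = len(x)
    if n == 0 or len(s) != n:
        raise MQTLError("positions and sds must be equal-length, non-empty")
    if np.any(s <= 0):
        raise MQTLError("all observation SDs must be positive")
    if not 1 <= K <= n:
        raise MQTLError(f"K must satisfy 1 <= K <= n={n}, got {K}")
    s2 = s ** 2

    if K == 1:
        mu = _weighted_mean(x, 1.0 / s2)
        loglik = float(np.sum(_log_density(x, s2, np.array([mu]))))
        return MixtureFit(
            K=1, means=np.array([mu]), weights=np.array([1.0]), loglik=loglik,
            responsibilities=np.ones((n, 1)), n_params=1, converged=True,
            n_iter=0, loglik_trace=[loglik], positions=x, sds=s,
        )

    rng = np.random.default_rng(seed)
    best: MixtureFit | None = None
    for _ in range(n_restarts):
        means = _init_means(x, K, rng)
        weights = np.full(K, 1.0 / K)
        trace: list[float] = []
        resp = np.full((n, K), 1.0 / K)
        converged = False
        for it in range(1, max_iter + 1):
            log_r = np.log(weights)[None, :] + _log_density(x, s2, means)
            row_norm = logsumexp(log_r, axis=1)
            loglik = float(row_norm.sum())
            resp = np.exp(log_r - row_norm[:, None])
            trace.append(loglik)
            if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
                converged = True
                break
            # M-step: precision-weighted means, average responsibilities
            w = resp / s2[:, None]
            denom = w.sum(axis=0)
            occupied = denom > 0
            means = np.where(occupied, (w * x[:, None]).sum(axis=0) / np.where(occupied, denom, 1.0), means)
            weights = resp.mean(axis=0)
        fit = MixtureFit(
            K=K, means=means, weights=weights, loglik=trace[-1],
            responsibilities=resp, n_params=2 * K - 1, converged=converged,
            n_iter=len(trace), loglik_trace=trace, positions=x, sds=s,
        )
        if best is None or fit.loglik > best.loglik:
            best = fit
    return best


def classification_loglik(fit: MixtureFit) -> float:
    """Mixture log-likelihood with each QTL hard-assigned to its argmax
    component (used by the AWE criterion)."""
    z = np.argmax(fit.responsibilities, axis=1)
    s2 = fit.sds ** 2
    logphi = _log_density(fit.positions, s2, fit.means)
    logw = np.log(np.maximum(fit.weights, 1e-300))
    return float(np.sum(logw[z] + logphi[np.arange(len(z)), z]))


def information_criteria(fit: MixtureFit, n: int) -> dict[str, float]:
    """AIC, AICc, AIC3, BIC, AWE for one fit (lower is better).

    AICc is undefined when n <= nu + 1 and is reported as +inf so it can
    never win the vote there.  AWE penalizes the classification
    log-likelihood (Banfield-Raftery form): -2 logL_c + 2 nu (3/2 + ln n).
    """
    nu = fit.n_params
    m2ll = -2.0 * fit.loglik
    aic = m2ll + 2.0 * nu
    aicc = aic + 2.0 * nu * (nu + 1) / (n - nu - 1) if n > nu + 1 else math.inf
    aic3 = m2ll + 3.0 * nu
    bic = m2ll + nu * math.log(n)
    awe = -2.0 * classification_loglik(fit) + 2.0 * nu * (1.5 + math.log(n))
    return {"AIC": aic, "AICc": aicc, "AIC3": aic3, "BIC": bic, "AWE": awe}


def select_model(fits: Mapping[int, MixtureFit], n: int,
                 strategy: str = "majority") -> ModelSelection:
    """Let each criterion vote for its minimizing K and combine the votes.

    ``majority``: most-voted K, ties toward smaller K.  ``aicc_only``: the
    AICc vote alone.  ``consensus_min``: smallest K any criterion voted for.
    """
    table: dict[str, dict[int, float]] = {c: {} for c in CRITERIA}
    for K in sorted(fits):
        values = information_criteria(fits[K], n)
        for c in CRITERIA:
            table[c][K] = values[c]
    votes = {
        c: min(per_k, key=lambda K: (per_k[K], K))
        for c, per_k in table.items()
    }
    chosen = combine_votes(votes, strategy)
    return ModelSelection(table=table, votes=votes, chosen_K=chosen, strategy=strategy)


def combine_votes(votes: Mapping[str, int], strategy: str = "majority") -> int:
    """Combine per-criterion K votes into one chosen K.

    ``majority`` takes the most-voted K with ties toward smaller K;
    ``aicc_only`` follows AICc alone; ``consensus_min`` takes the smallest
    K any criterion voted for.
    """
    if strategy == "majority":
        counts: dict[int, int] = {}
        for K in votes.values():
            counts[K] = counts.get(K, 0) + 1
        return min(counts, key=lambda K: (-counts[K], K))
    if strategy == "aicc_only":
        return votes["AICc"]
    if strategy == "consensus_min":
        return min(votes.values())
    raise ValueError(f"unknown selection strategy {strategy!r}")


def flanking_markers(reference: GeneticMap, chromosome: str,
                     ci_start: float, ci_end: float) -> tuple[str | None, str | None]:
    """Nearest reference markers at/outside the CI bounds (terminal marker
    when the CI reaches past the mapped ends)."""
    if chromosome not in reference.markers:
        return None, None
    loci = reference.loci(chromosome)
    left = None
    for m in loci:
        if m.position <= ci_start:
            left = m.name
        else:
            break
    if left is None and loci:
        left = loci[0].name
    right = None
    for m in reversed(loci):
        if m.position >= ci_end:
            right = m.name
        else:
            break
    if right is None and loci:
        right = loci[-1].name
    return left, right


def declare_mqtl(fit: MixtureFit, qtls: Sequence[ProjectedQTL], tissue_class: str,
                 reference: GeneticMap, start_ordinal: int = 1) -> list[MQTL]:
    """Turn the chosen fit into MQTL records for one chromosome.

    Each QTL goes to its argmax-responsibility component.  An MQTL's
    position is the inverse-variance weighted mean of its members
    (weights 1/s_i^2), its sd the combined precision sqrt(1/sum 1/s_i^2),
    and its 95% CI position +/- 1.96 sd.  Empty components (possible after
    hardening) are dropped.  MQTL are named <PREFIX><ordinal> in position
    order, PREFIX being LIR/SIR/KIR for leaf/stem/kernel.
    """
    if len(qtls) != len(fit.positions):
        raise MQTLError("fit and QTL list are inconsistent")
    prefix = TISSUE_PREFIX.get(tissue_class, tissue_class.upper())
    z = np.argmax(fit.responsibilities, axis=1)
    clusters = []
    for k in range(fit.K):
        idx = np.where(z == k)[0]
        if len(idx) == 0:
            continue
        prec = 1.0 / fit.sds[idx] ** 2
        pos = _weighted_mean(fit.positions[idx], prec)
        sd = float(math.sqrt(1.0 / prec.sum()))
        members = [
            (qtls[i].qtl_id, float(fit.responsibilities[i, k])) for i in idx
        ]
        clusters.append((pos, sd, members))
    clusters.sort(key=lambda c: c[0])
    out = []
    chromosome = qtls[0].chromosome
    for ordinal, (pos, sd, members) in enumerate(clusters, start=start_ordinal):
        lo, hi = pos - Z95 * sd, pos + Z95 * sd
        left, right = flanking_markers(reference, chromosome, lo, hi)
        out.append(MQTL(
            mqtl_id=f"{prefix}{ordinal}", tissue_class=tissue_class,
            chromosome=chromosome, position=pos, ci95_start=lo, ci95_end=hi,
            sd=sd, members=members, flank_left=left, flank_right=right,
        ))
    return out


@dataclass
class MetaResult:
    """All MQTL for one tissue plus the per-chromosome model selections."""

    mqtls: list[MQTL]
    selections: dict[str, ModelSelection]
    fits: dict[str, MixtureFit]


def run_meta(projected: Sequence[ProjectedQTL], tissue_class: str,
             reference: GeneticMap, seed: int = 0, kmax: int = 10,
             strategy: str = "majority", n_restarts: int = 10) -> MetaResult:
    """Per-chromosome meta-analysis for one tissue class.

    Only successfully projected QTL of the requested tissue enter.  Each
    chromosome is fit for K = 1..min(kmax, n), the criteria vote, and the
    winning fit's components become MQTL, renumbered consecutively across
    chromosomes in chromosome-then-position order.
    """
    pool = [q for q in projected
            if q.tissue_class == tissue_class and q.projection_status == "projected"]
    by_chrom: dict[str, list[ProjectedQTL]] = {}
    for q in pool:
        by_chrom.setdefault(q.chromosome, []).append(q)

    mqtls: list[MQTL] = []
    selections: dict[str, ModelSelection] = {}
    best_fits: dict[str, MixtureFit] = {}
    ordinal = 1
    seed_seq = np.random.SeedSequence(seed)
    chrom_order = sorted(by_chrom, key=natural_chrom_key)
    chrom_seeds = {c: int(s.generate_state(1)[0] % (2 ** 31))
                   for c, s in zip(chrom_order, seed_seq.spawn(len(chrom_order)))}
    for chrom in chrom_order:
        qtls = sorted(by_chrom[chrom], key=lambda q: (q.ref_position, q.qtl_id))
        positions = [q.ref_position for q in qtls]
        sds = [qtl_sd(q.ref_ci_end - q.ref_ci_start) for q in qtls]
        n = len(qtls)
        fits = {
            K: fit_mixture(positions, sds, K, seed=chrom_seeds[chrom] + K,
                           n_restarts=n_restarts)
            for K in range(1, min(kmax, n) + 1)
        }
        sel = select_model(fits, n, strategy=strategy)
        selections[chrom] = sel
        best_fits[chrom] = fits[sel.chosen_K]
        declared = declare_mqtl(fits[sel.chosen_K], qtls, tissue_class,
                                reference, start_ordinal=ordinal)
        ordinal += len(declared)
        mqtls.extend(declared)
    return MetaResult(mqtls=mqtls, selections=selections, fits=best_fits)
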