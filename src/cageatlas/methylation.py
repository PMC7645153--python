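"""WGBS CpG methylation: symmetric merge, Beta-Binomial HMM, HMR calling.

Per-cytosine counts (CGmap dialect) are merged across the two strands
of each CpG dinucleotide, filtered to >=10x coverage, and segmented
with a two-state hidden Markov model whose emissions are
Beta-Binomial(alpha_s, beta_s) — methylated-count likelihoods that
account for read coverage at each site.  Baum-Welch EM fits the
transition matrix in closed form and the emission shapes by numerical
maximisation; Viterbi decoding yields hypomethylated regions (runs of
>= min_cpgs hypo-state CpGs, extended 2 bp past the last CpG to cover
the dinucleotide).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numba import njit
from scipy.optimize import minimize
from scipy.special import betaln, gammaln


class MethylationError(ValueError):
    pass


# ---------------------------------------------------------------- CpG tracks


@dataclass
class CpGRecord:
    contig: str
    strand: str
    position: int
    context: str
    methylated: int
    coverage: int


@dataclass
class CpGTrack:
    """Symmetric-merged per-CpG counts, sorted per contig."""

    sample_id: str
    contigs: dict[str, pd.DataFrame]  # columns: position, methylated, coverage
    min_coverage: int = 10

    def filtered(self) -> dict[str, pd.DataFrame]:
        """Records meeting the coverage minimum (HMM input)."""
        return {
            c: df[df["coverage"] >= self.min_coverage].reset_index(drop=True)
            for c, df in self.contigs.items()
        }

    @property
    def n_sites(self) -> int:
        return sum(len(df) for df in self.contigs.values())


def read_cgmap(path: str | os.PathLike, sample_id: str | None = None) -> list[CpGRecord]:
    """Read a CGmap-dialect TSV.

    Columns: contig, nucleotide (C=+ strand, G=- strand), position
    (1-based), context, dinucleotide context, methylation level,
    methylated count, coverage.
    """
    records = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 8:
                raise MethylationError(f"{path}:{ln}: expected 8 columns")
            strand = "+" if f[1] == "C" else "-"
            records.append(
                CpGRecord(
                    contig=f[0],
                    strand=strand,
                    position=int(f[2]) - 1,
                    context=f[3],
                    methylated=int(f[6]),
                    coverage=int(f[7]),
                )
            )
    return records


def write_cgmap(records: list[CpGRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for r in records:
            nt = "C" if r.strand == "+" else "G"
            level = r.methylated / r.coverage if r.coverage else 0.0
            fh.write(
                f"{r.contig}\t{nt}\t{r.position + 1}\t{r.context}\tCG\t"
                f"{level:.4f}\t{r.methylated}\t{r.coverage}\n"
            )


def merge_symmetric_cpgs(
    records: list[CpGRecord], sample_id: str = "", min_coverage: int = 10
) -> CpGTrack:
    """Merge the two cytosines of each CpG dinucleotide.

    A + strand C at p pairs with the - strand C at p+1; counts are
    summed and reported at p.  Lone cytosines are kept as-is.  Only
    CpG-context records are used.
    """
    by_contig: dict[str, dict[int, list[int]]] = {}
    for r in records:
        if not r.context.startswith("CG"):
            continue
        p = r.position if r.strand == "+" else r.position - 1
        d = by_contig.setdefault(r.contig, {})
        if p in d:
            d[p][0] += r.methylated
            d[p][1] += r.coverage
        else:
            d[p] = [r.methylated, r.coverage]
    contigs = {}
    for contig, d in by_contig.items():
        pos = np.array(sorted(d), dtype=np.int64)
        contigs[contig] = pd.DataFrame(
            {
                "position": pos,
                "methylated": [d[p][0] for p in pos],
                "coverage": [d[p][1] for p in pos],
            }
        )
    return CpGTrack(sample_id=sample_id, contigs=contigs, min_coverage=min_coverage)


# ---------------------------------------------------------- emission density


def betabinom_logpmf(m, n, alpha: float, beta: float):
    """log P(m | n, alpha, beta) under the Beta-Binomial distribution.

    log C(n, m) + log B(m + alpha, n - m + beta) - log B(alpha, beta).
    Accepts scalars or arrays for m, n.
    """
    if alpha <= 0 or beta <= 0:
        raise MethylationError("alpha and beta must be positive")
    m = np.asarray(m)
    n = np.asarray(n)
    if np.any(m < 0) or np.any(m > n):
        raise MethylationError("need 0 <= m <= n")
    logc = gammaln(n + 1) - gammaln(m + 1) - gammaln(n - m + 1)
    out = logc + betaln(m + alpha, n - m + beta) - betaln(alpha, beta)
    return out if out.ndim else float(out)


# ------------------------------------------------------------------ HMM core


@njit(cache=False)
def _forward_backward(logB, logA, logpi):  # pragma: no cover - numba
    T, K = logB.shape
    alpha = np.empty((T, K))
    beta = np.empty((T, K))
    c = np.empty(T)
    # scaled forward
    a0 = np.exp(logpi + logB[0])
    c[0] = a0.sum()
    alpha[0] = a0 / c[0]
    A = np.exp(logA)
    for t in range(1, T):
        bt = np.exp(logB[t] - logB[t].max())
        at = (alpha[t - 1] @ A) * bt
        s = at.sum()
        alpha[t] = at / s
        c[t] = s * np.exp(logB[t].max())
    beta[T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        btn = np.exp(logB[t + 1] - logB[t + 1].max())
        bt = A @ (btn * beta[t + 1])
        beta[t] = bt / bt.sum()
    return alpha, beta, c


@njit(cache=False)
def _viterbi(logB, logA, logpi):  # pragma: no cover - numba
    T, K = logB.shape
    delta = logpi + logB[0]
    psi = np.zeros((T, K), dtype=np.int64)
    for t in range(1, T):
        nd = np.empty(K)
        for j in range(K):
            best = delta[0] + logA[0, j]
            arg = 0
            for i in range(1, K):
                v = delta[i] + logA[i, j]
                if v > best:
                    best = v
                    arg = i
            nd[j] = best + logB[t, j]
            psi[t, j] = arg
        delta = nd
    path = np.empty(T, dtype=np.int64)
    path[T - 1] = np.argmax(delta)
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]
    return path


def _fb_loglik_posteriors(logB, logA, logpi):
    """Scaled forward-backward: posteriors, xi sums and log-likelihood."""
    alpha, beta, c = _forward_backward(logB, logA, logpi)
    T, K = logB.shape
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    A = np.exp(logA)
    # expected transition counts
    xi = np.zeros((K, K))
    for t in range(T - 1):
        b = np.exp(logB[t + 1] - logB[t + 1].max())
        M = (alpha[t][:, None] * A) * (b * beta[t + 1])[None, :]
        xi += M / M.sum()
    ll = float(np.sum(np.log(c)))
    return gamma, xi, ll


@dataclass
class HMMParams:
    """Two-state Beta-Binomial HMM parameters and EM controls."""

    alpha: tuple[float, float] = (2.0, 8.0)  # hypo, hyper init (means .2/.8)
    beta: tuple[float, float] = (8.0, 2.0)
    self_transition: float = 0.99
    em_tol: float = 1e-4
    max_iter: int = 100
    min_cpgs: int = 3
    desert_size: int = 1000


@dataclass
class HMRSet:
    """Hypomethylated regions from Viterbi segmentation."""

    regions: pd.DataFrame  # contig, start, end, n_cpgs, score, mean_methylation
    sample_id: str = ""

    def __len__(self):
        return len(self.regions)

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for r in self.regions.itertuples():
                fh.write(
                    f"{r.contig}\t{r.start}\t{r.end}\tHMR\t{r.n_cpgs}\t.\n"
                )


class BetaBinomialHMM:
    """Two-state (hypo / hyper) Beta-Binomial HMM fit by Baum-Welch.

    Emission shapes are re-estimated each EM iteration by numerically
    maximising the posterior-weighted expected log-likelihood (duplicate
    (m, n) observations are collapsed with summed weights, which is
    exact).  States are relabelled after fitting so the hypo state has
    the smaller mean alpha/(alpha+beta).
    """

    def __init__(self, params: HMMParams | None = None):
        self.params = params or HMMParams()
        p = self.params
        self.alpha_ = np.array(p.alpha, dtype=float)
        self.beta_ = np.array(p.beta, dtype=float)
        st = p.self_transition
        self.transmat_ = np.array([[st, 1 - st], [1 - st, st]])
        self.startprob_ = np.array([0.5, 0.5])
        self.converged_ = False
        self.loglik_trace_: list[float] = []

    # -- internals

    def _log_emissions(self, m: np.ndarray, n: np.ndarray) -> np.ndarray:
        out = np.empty((len(m), 2))
        for k in range(2):
            out[:, k] = betabinom_logpmf(m, n, self.alpha_[k], self.beta_[k])
        return out

    @staticmethod
    def _optimize_state(m, n, weights, alpha0, beta0):
        """Maximise sum_i w_i * logpmf(m_i, n_i | a, b) over (a, b) > 0."""
        pairs, inv = np.unique(np.stack([m, n], axis=1), axis=0, return_inverse=True)
        w = np.bincount(inv, weights=weights, minlength=len(pairs))
        mu, nu = pairs[:, 0].astype(float), pairs[:, 1].astype(float)
        logc = gammaln(nu + 1) - gammaln(mu + 1) - gammaln(nu - mu + 1)

        def neg(theta):
            a, b = np.exp(theta)
            ll = logc + betaln(mu + a, nu - mu + b) - betaln(a, b)
            return -float(np.dot(w, ll))

        res = minimize(
            neg,
            np.log([alpha0, beta0]),
            method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 400},
        )
        return np.exp(res.x)

    def fit(self, chains: list[tuple[np.ndarray, np.ndarray]]) -> "BetaBinomialHMM":
        """EM over one or more (methylated, coverage) observation chains."""
        p = self.params
        chains = [(np.asarray(m), np.asarray(n)) for m, n in chains if len(m) > 0]
        if not chains:
            raise MethylationError("no observations")
        prev_ll = -np.inf
        self.loglik_trace_ = []
        for _ in range(p.max_iter):
            total_ll = 0.0
            xi_sum = np.zeros((2, 2))
            gamma0 = np.zeros(2)
            gammas = []
            logA = np.log(self.transmat_)
            logpi = np.log(self.startprob_)
            for m, n in chains:
                logB = self._log_emissions(m, n)
                gamma, xi, ll = _fb_loglik_posteriors(logB, logA, logpi)
                total_ll += ll
                xi_sum += xi
                gamma0 += gamma[0]
                gammas.append(gamma)
            self.loglik_trace_.append(total_ll)
            if total_ll - prev_ll < p.em_tol and len(self.loglik_trace_) > 1:
                self.converged_ = True
                break
            prev_ll = total_ll
            # M-step: closed-form transitions / pi
            self.startprob_ = gamma0 / gamma0.sum()
            denom = xi_sum.sum(axis=1, keepdims=True)
            if np.all(denom > 0):
                self.transmat_ = xi_sum / denom
            self.transmat_ = np.clip(self.transmat_, 1e-10, None)
            self.transmat_ /= self.transmat_.sum(axis=1, keepdims=True)
            # M-step: emission shapes by numerical maximisation
            allm = np.concatenate([m for m, _ in chains])
            alln = np.concatenate([n for _, n in chains])
            allg = np.concatenate(gammas, axis=0)
            for k in range(2):
                self.alpha_[k], self.beta_[k] = self._optimize_state(
                    allm, alln, allg[:, k], self.alpha_[k], self.beta_[k]
                )
        self._relabel()
        return self

    def _relabel(self):
        means = self.alpha_ / (self.alpha_ + self.beta_)
        if means[0] > means[1]:  # enforce hypo = state 0
            order = [1, 0]
            self.alpha_ = self.alpha_[order]
            self.beta_ = self.beta_[order]
            self.startprob_ = self.startprob_[order]
            self.transmat_ = self.transmat_[np.ix_(order, order)]

    @property
    def state_means_(self) -> np.ndarray:
        return self.alpha_ / (self.alpha_ + self.beta_)

    def posterior_hypo(self, m: np.ndarray, n: np.ndarray) -> np.ndarray:
        logB = self._log_emissions(np.asarray(m), np.asarray(n))
        gamma, _, _ = _fb_loglik_posteriors(
            logB, np.log(self.transmat_), np.log(self.startprob_)
        )
        return gamma[:, 0]

    def loglik(self, m: np.ndarray, n: np.ndarray) -> float:
        logB = self._log_emissions(np.asarray(m), np.asarray(n))
        _, _, ll = _fb_loglik_posteriors(
            logB, np.log(self.transmat_), np.log(self.startprob_)
        )
        return ll

    def decode(self, m: np.ndarray, n: np.ndarray) -> np.ndarray:
        logB = self._log_emissions(np.asarray(m), np.asarray(n))
        return _viterbi(logB, np.log(self.transmat_), np.log(self.startprob_))


def _split_chains(df: pd.DataFrame, desert_size: int) -> list[pd.DataFrame]:
    if len(df) == 0:
        return []
    pos = df["position"].to_numpy()
    breaks = np.nonzero(np.diff(pos) > desert_size)[0] + 1
    return [df.iloc[idx] for idx in np.split(np.arange(len(df)), breaks)]


def fit_and_segment(
    track: CpGTrack, params: HMMParams | None = None
) -> tuple[HMRSet, BetaBinomialHMM, dict[str, np.ndarray]]:
    """Fit the HMM to a coverage-filtered track and call HMRs.

    Returns (regions, fitted model, per-contig posterior hypo
    probabilities over the filtered CpGs).  Contig chains are broken at
    CpG gaps larger than ``desert_size``; hypo runs shorter than
    ``min_cpgs`` are dropped; region ends extend 2 bp past the last CpG.
    """
    params = params or HMMParams()
    filtered = track.filtered()
    chains = []
    chain_meta = []  # (contig, dataframe)
    for contig in sorted(filtered):
        for chunk in _split_chains(filtered[contig], params.desert_size):
            if len(chunk) == 0:
                continue
            chains.append(
                (
                    chunk["methylated"].to_numpy(),
                    chunk["coverage"].to_numpy(),
                )
            )
            chain_meta.append((contig, chunk))
    if sum(len(m) for m, _ in chains) < 50:
        raise MethylationError("need >= 50 covered CpGs to fit the HMM")

    model = BetaBinomialHMM(params).fit(chains)

    rows = []
    posteriors: dict[str, list[np.ndarray]] = {}
    for (contig, chunk), (m, n) in zip(chain_meta, chains):
        states = model.decode(m, n)
        post = model.posterior_hypo(m, n)
        posteriors.setdefault(contig, []).append(post)
        pos = chunk["position"].to_numpy()
        is_hypo = states == 0
        if not is_hypo.any():
            continue
        edges = np.nonzero(np.diff(is_hypo.astype(int)))[0] + 1
        start_idx = 0
        for seg in np.split(np.arange(len(states)), edges):
            if not is_hypo[seg[0]] or len(seg) < params.min_cpgs:
                continue
            i0, i1 = seg[0], seg[-1]
            rows.append(
                (
                    contig,
                    int(pos[i0]),
                    int(pos[i1]) + 2,
                    int(len(seg)),
                    float(post[seg].sum()),
                    float(m[seg].sum() / max(1, n[seg].sum())),
                )
            )
    regions = pd.DataFrame(
        rows,
        columns=["contig", "start", "end", "n_cpgs", "score", "mean_methylation"],
    ).sort_values(["contig", "start"]).reset_index(drop=True)
    post_by_contig = {
        c: np.concatenate(v) for c, v in posteriors.items()
    }
    return HMRSet(regions, sample_id=track.sample_id), model, post_by_contig


def validate_tss(
    clusters: pd.DataFrame, novel_flags: np.ndarray, hmrs: HMRSet
) -> tuple[pd.Series, dict]:
    """Cross annotated/novel TSS clusters with hypomethylated regions.

    ``clusters`` needs contig/start/end columns; a >=1 bp overlap with
    any HMR marks a cluster +HypoCpG.  Returns per-cluster categories
    and the four-way percentage summary.
    """
    hmr_by_contig: dict[str, np.ndarray] = {}
    for contig, sub in hmrs.regions.groupby("contig"):
        hmr_by_contig[contig] = sub[["start", "end"]].to_numpy()
    cats = []
    for row, novel in zip(clusters.itertuples(), novel_flags):
        ivs = hmr_by_contig.get(row.contig)
        hypo = False
        if ivs is not None:
            hypo = bool(np.any((ivs[:, 0] < row.end) & (ivs[:, 1] > row.start)))
        label = ("novel" if novel else "annotated") + (
            "+HypoCpG" if hypo else " w/o"
        )
        cats.append(label)
    cats = pd.Series(cats, index=clusters.index, name="category")
    n_novel = int(novel_flags.sum())
    n_annot = len(cats) - n_novel
    summary = {
        "n_annotated": n_annot,
        "n_novel": n_novel,
        "pct_annotated_hypo": 100.0
        * (cats == "annotated+HypoCpG").sum() / max(1, n_annot),
        "pct_novel_hypo": 100.0 * (cats == "novel+HypoCpG").sum() / max(1, n_novel),
    }
    return cats, summary


def write_posterior_bedgraph(
    track: CpGTrack, posteriors: dict[str, np.ndarray], path
) -> None:
    """Per-CpG hypomethylation-score (posterior) track."""
    filtered = track.filtered()
    with open(path, "w") as fh:
        for contig in sorted(posteriors):
            pos = filtered[contig]["position"].to_numpy()
            for p, v in zip(pos, posteriors[contig]):
                fh.write(f"{contig}\t{p}\t{p + 2}\t{v:.4f}\n")
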