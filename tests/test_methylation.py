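"""Symmetric CpG merge, Beta-Binomial emissions, HMM fitting and HMR calls."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats
from scipy.special import comb

from cageatlas import methylation as meth
from cageatlas import simulate as sim


def test_symmetric_merge_adds_strand_counts():
    records = [
        meth.CpGRecord("chr1", "+", 100, "CG", 3, 6),
        meth.CpGRecord("chr1", "-", 101, "CG", 2, 4),
        meth.CpGRecord("chr1", "+", 500, "CG", 0, 12),  # lone cytosine
        meth.CpGRecord("chr1", "+", 600, "CHH", 5, 9),  # non-CpG ignored
    ]
    track = meth.merge_symmetric_cpgs(records)
    df = track.contigs["chr1"]
    assert df[df.position == 100].iloc[0].tolist() == [100, 5, 10]
    assert df[df.position == 500].iloc[0].tolist() == [500, 0, 12]
    assert 600 not in set(df["position"])


def test_cgmap_round_trip(tmp_path):
    records = [
        meth.CpGRecord("chr1", "+", 10, "CG", 2, 8),
        meth.CpGRecord("chr1", "-", 11, "CG", 5, 6),
    ]
    path = tmp_path / "x.cgmap.tsv"
    meth.write_cgmap(records, path)
    back = meth.read_cgmap(path)
    assert [(r.contig, r.strand, r.position, r.methylated, r.coverage)
            for r in back] == [
        ("chr1", "+", 10, 2, 8), ("chr1", "-", 11, 5, 6)
    ]


def test_betabinom_uniform_and_empty_cases():
    # alpha = beta = 1 makes every outcome of n trials equally likely
    assert meth.betabinom_logpmf(5, 10, 1, 1) == pytest.approx(
        np.log(1 / 11), abs=1e-10
    )
    assert meth.betabinom_logpmf(0, 0, 3.2, 1.7) == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(meth.MethylationError):
        meth.betabinom_logpmf(5, 4, 1, 1)
    with pytest.raises(meth.MethylationError):
        meth.betabinom_logpmf(1, 4, -1, 1)


def test_betabinom_matches_quadrature_and_scipy():
    m, n, a, b = 3, 8, 2.0, 5.0
    dens = stats.beta(a, b).pdf
    integral, _ = integrate.quad(
        lambda p: comb(n, m) * p**m * (1 - p) ** (n - m) * dens(p), 0, 1
    )
    assert meth.betabinom_logpmf(m, n, a, b) == pytest.approx(
        np.log(integral), abs=1e-8
    )
    grid = [(0, 5, 0.7, 3.1), (12, 20, 9, 1), (7, 7, 1.5, 1.5)]
    for m, n, a, b in grid:
        assert meth.betabinom_logpmf(m, n, a, b) == pytest.approx(
            stats.betabinom(n, a, b).logpmf(m), abs=1e-10
        )


def _synthetic_chain(seed=3, n=3000):
    rng = np.random.default_rng(seed)
    A = np.array([[0.98, 0.02], [0.02, 0.98]])
    return sim.simulate_hmm_chain((1, 9), (9, 1), A, n, 20, rng)


def test_em_loglik_non_decreasing():
    _, m, n = _synthetic_chain()
    model = meth.BetaBinomialHMM(meth.HMMParams(max_iter=15))
    model.fit([(m, n)])
    trace = np.array(model.loglik_trace_)
    assert np.all(np.diff(trace) >= -1e-6)


def test_posteriors_sum_to_one_and_fb_agrees():
    _, m, n = _synthetic_chain(seed=9, n=800)
    model = meth.BetaBinomialHMM(meth.HMMParams(max_iter=5)).fit([(m, n)])
    logB = model._log_emissions(m, n)
    gamma, _, ll = meth._fb_loglik_posteriors(
        logB, np.log(model.transmat_), np.log(model.startprob_)
    )
    assert np.allclose(gamma.sum(axis=1), 1.0, atol=1e-10)
    # likelihood from the recursion matches direct log-sum-exp on a prefix
    k = 12
    from itertools import product

    best = -np.inf
    tot = []
    for path in product([0, 1], repeat=k):
        lp = np.log(model.startprob_[path[0]]) + logB[0, path[0]]
        for t in range(1, k):
            lp += np.log(model.transmat_[path[t - 1], path[t]]) + logB[t, path[t]]
        tot.append(lp)
    direct = np.logaddexp.reduce(tot)
    _, _, ll_prefix = meth._fb_loglik_posteriors(
        logB[:k], np.log(model.transmat_), np.log(model.startprob_)
    )
    assert ll_prefix == pytest.approx(direct, abs=1e-8)


def test_state_mean_recovery_at_scale():
    """EM recovers the two state means within 0.05 at 1e4 CpGs."""
    _, m, n = _synthetic_chain(seed=21, n=10_000)
    model = meth.BetaBinomialHMM().fit([(m, n)])
    means = model.state_means_
    assert means[0] == pytest.approx(0.1, abs=0.05)
    assert means[1] == pytest.approx(0.9, abs=0.05)


def test_fully_methylated_track_has_no_hmrs():
    n = np.full(200, 20)
    m = n.copy()
    pos = np.arange(200) * 30
    track = meth.CpGTrack(
        "s", {"chr1": pd.DataFrame(
            {"position": pos, "methylated": m, "coverage": n})}
    )
    hmrs, model, _ = meth.fit_and_segment(track)
    assert len(hmrs) == 0


def test_segmentation_ignores_low_coverage_sites():
    rng = np.random.default_rng(6)
    _, m, n = _synthetic_chain(seed=6, n=2000)
    pos = np.cumsum(rng.integers(10, 40, size=2000))
    base = pd.DataFrame({"position": pos, "methylated": m, "coverage": n})
    track = meth.CpGTrack("s", {"chr1": base})
    hmrs_a, _, _ = meth.fit_and_segment(track)
    # interleave sites below the coverage floor; calls must not change
    extra = pd.DataFrame(
        {
            "position": pos + 3,
            "methylated": rng.integers(0, 5, 2000),
            "coverage": np.full(2000, 5),
        }
    )
    merged = (
        pd.concat([base, extra]).sort_values("position").reset_index(drop=True)
    )
    hmrs_b, _, _ = meth.fit_and_segment(meth.CpGTrack("s", {"chr1": merged}))
    pd.testing.assert_frame_equal(hmrs_a.regions, hmrs_b.regions)


def test_planted_islands_recovered(default_panel):
    truth, outdir = default_panel
    cgmap = sorted((outdir / "wgbs").glob("*.cgmap.tsv"))[0]
    track = meth.merge_symmetric_cpgs(meth.read_cgmap(cgmap), sample_id="t1")
    hmrs, model, post = meth.fit_and_segment(track)
    called = [
        (r.contig, r.start, r.end) for r in hmrs.regions.itertuples()
    ]
    rec = sim.score_interval_recovery(truth.hmr_islands, called)
    assert rec.recall >= 0.95
    assert rec.mean_jaccard >= 0.85
    for arr in post.values():
        assert np.all((arr >= 0) & (arr <= 1))


def test_validate_tss_categories():
    clusters = pd.DataFrame(
        {
            "contig": ["chr1"] * 4,
            "start": [100, 100, 900, 900],
            "end": [110, 110, 910, 910],
        }
    )
    hmrs = meth.HMRSet(
        pd.DataFrame(
            {"contig": ["chr1"], "start": [50], "end": [200],
             "n_cpgs": [10], "score": [9.0], "mean_methylation": [0.05]}
        )
    )
    flags = np.array([False, True, False, True])
    cats, summary = meth.validate_tss(clusters, flags, hmrs)
    assert list(cats) == [
        "annotated+HypoCpG", "novel+HypoCpG", "annotated w/o", "novel w/o"
    ]
    assert summary["pct_novel_hypo"] == 50.0
    assert summary["pct_annotated_hypo"] == 50.0
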