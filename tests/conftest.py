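"""Shared fixtures: one default synthetic panel, analysed once per session."""

from types import SimpleNamespace

import pytest

from cageatlas import clustering as cl
from cageatlas import genome as gn
from cageatlas import pipeline as pl
from cageatlas import simulate as sim
from cageatlas import tags as tg

PANEL_SEED = 101


@pytest.fixture(scope="session")
def default_panel(tmp_path_factory):
    """Synthetic tissue panel at generator defaults (fixed seed)."""
    outdir = tmp_path_factory.mktemp("panel")
    truth = sim.generate(sim.GeneratorConfig(seed=PANEL_SEED), outdir)
    return truth, outdir


@pytest.fixture(scope="session")
def panel_analysis(default_panel):
    """Loaded inputs plus called/filtered clusters for the default panel."""
    truth, outdir = default_panel
    rc = pl.RunConfig(input_dir=str(outdir))
    contigs, models, profiles = pl.load_inputs(rc)
    pooled = tg.pool_profiles(profiles, mode=rc.pooling_mode)
    unfiltered = cl.call_unidirectional_clusters(pooled, profiles, rc.clustering)
    filtered, attrition = cl.filter_clusters(unfiltered, rc.clustering)
    index = gn.build_region_index(models, contigs, rc.region)
    return SimpleNamespace(
        truth=truth,
        outdir=outdir,
        config=rc,
        contigs=contigs,
        models=models,
        profiles=profiles,
        pooled=pooled,
        unfiltered=unfiltered,
        filtered=filtered,
        attrition=attrition,
        index=index,
    )


@pytest.fixture(scope="session")
def pipeline_run(default_panel, tmp_path_factory):
    """Full end-to-end pipeline output on the default panel."""
    truth, outdir = default_panel
    out = tmp_path_factory.mktemp("pipeline_out")
    summary = pl.run_all(pl.RunConfig(input_dir=str(outdir)), out)
    return truth, out, summary


@pytest.fixture()
def toy_models():
    """Three genes on one 20 kb contig, both strands."""
    contigs = gn.ContigSet.from_pairs([("chr1", 20_000)])
    models = [
        gn.TranscriptModel(
            "tx0", "geneA", "chr1", "+",
            exons=[(2000, 2400), (3000, 3600)],
            cds=[(2200, 2400), (3000, 3400)],
        ),
        gn.TranscriptModel(
            "tx1", "geneB", "chr1", "-",
            exons=[(8000, 8500), (9000, 9500)],
            cds=[(8200, 8500), (9000, 9300)],
        ),
        gn.TranscriptModel(
            "tx2", "geneC", "chr1", "+",
            exons=[(15_000, 15_800)],
        ),
    ]
    return contigs, models
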