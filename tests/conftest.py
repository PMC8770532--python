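import numpy as np
import pandas as pd
import pytest

import glucoshift as gs


@pytest.fixture
def config():
    return gs.AnalysisConfig()


def make_matrix(counts, conditions, gene_ids=None, lengths=None):
    """Build a CountMatrix from a 2-D array and per-sample condition labels."""
    counts = np.asarray(counts)
    n_genes, n_samples = counts.shape
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(1, n_genes + 1)]
    reps = {}
    sample_ids, rows = [], []
    for label in conditions:
        reps[label] = reps.get(label, 0) + 1
        sample_ids.append(f"{label}_{reps[label]}")
        rows.append((label, reps[label]))
    meta = pd.DataFrame(rows, columns=["condition", "replicate"], index=sample_ids)
    eff = None if lengths is None else pd.Series(lengths, index=gene_ids, dtype=float)
    return gs.CountMatrix(
        counts=pd.DataFrame(counts, index=gene_ids, columns=sample_ids),
        sample_meta=meta,
        effective_lengths=eff,
    )


@pytest.fixture
def small_matrix():
    """3 genes x 12 samples (all four conditions in triplicate)."""
    rng = np.random.default_rng(0)
    counts = rng.poisson(50, size=(3, 12))
    return make_matrix(counts, ["LL"] * 3 + ["HH"] * 3 + ["L2H"] * 3 + ["H2L"] * 3)


@pytest.fixture(scope="session")
def default_study():
    """One full-scale synthetic study shared by the expensive tests.

    Runs the generator at study defaults (9,277 genes) and the three DEG
    comparisons once per session; returns everything downstream tests
    need (truth, DEG lists, GSR records, Venn summary, pathway map).
    """
    spec = gs.TranscriptomeSimSpec(rng_seed=1)
    matrix, truth = gs.simulate_transcriptome(spec)
    pmap, truth = gs.simulate_pathway_map(truth, rng_seed=2)
    config = gs.AnalysisConfig()
    deg_lists = gs.build_comparisons(matrix, config)
    gsr_records, venn = gs.identify_gsr(deg_lists, config)
    return {
        "spec": spec,
        "matrix": matrix,
        "truth": truth,
        "pmap": pmap,
        "config": config,
        "deg_lists": deg_lists,
        "gsr_records": gsr_records,
        "venn": venn,
    }
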