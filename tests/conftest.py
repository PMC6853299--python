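import pandas as pd
import pytest

from hybridreg import expression, simulate


@pytest.fixture(scope="session")
def balanced_dataset():
    """A 400-gene simulated experiment with equal category proportions,
    plus the derived ratio tables the classifiers consume."""
    cfg = simulate.SimulationConfig(
        n_genes=400, seed=42,
        class_proportions={"cis": 0.25, "trans": 0.25,
                           "cis_and_trans": 0.25, "conserved": 0.25})
    arch, counts = simulate.simulate_dataset(cfg)
    all_counts = pd.concat([counts.parental_counts, counts.f1_counts], axis=1)
    expr = expression.rpkm(all_counts, counts.gene_lengths,
                           counts.library_sizes)
    y = expression.allelic_log_ratios(counts.allele_counts)
    x = expression.parental_log_ratio(expr, counts.groups)
    parental = expression.parental_pairwise_ratios(expr, counts.groups)
    return {"config": cfg, "arch": arch, "counts": counts, "expr": expr,
            "y": y, "x": x, "parental": parental}
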