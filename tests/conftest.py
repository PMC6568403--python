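import numpy as np
import pytest

from metasig import ExpressionMatrix


@pytest.fixture
def tiny_matrix():
    """3 genes x 4 samples, two classes, already on log2 scale."""
    return ExpressionMatrix(
        gene_ids=["g1", "g2", "g3"],
        sample_ids=["s1", "s2", "s3", "s4"],
        values=np.array(
            [
                [1.0, 2.0, 3.0, 4.0],
                [4.0, 3.0, 2.0, 1.0],
                [0.0, 0.5, 1.0, 1.5],
            ]
        ),
        labels={"s1": "A", "s2": "A", "s3": "B", "s4": "B"},
        log2_transformed=True,
    )


def separating_matrix(values_a, values_b, k_genes: int = 1) -> ExpressionMatrix:
    """One-gene (replicated) matrix with class A at values_a, class B at values_b."""
    vals = list(values_a) + list(values_b)
    samples = [f"s{i}" for i in range(len(vals))]
    labels = {s: ("A" if i < len(values_a) else "B") for i, s in enumerate(samples)}
    return ExpressionMatrix(
        gene_ids=[f"g{j}" for j in range(k_genes)],
        sample_ids=samples,
        values=np.tile(np.array(vals, dtype=float), (k_genes, 1)),
        labels=labels,
        log2_transformed=True,
    )
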