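import numpy as np
import pandas as pd
import pytest

import screenforge as sf


@pytest.fixture(scope="session")
def toy_reference() -> sf.LibraryReference:
    """Six targeting sgRNAs over three genes plus four non-targeting controls."""
    rng = np.random.default_rng(123)
    bases = np.array(list("ACGT"))
    seqs = ["".join(bases[rng.integers(0, 4, 20)]) for _ in range(10)]
    return sf.LibraryReference(
        pd.DataFrame(
            {
                "sgrna_sequence": seqs,
                "sgrna_id": [f"sg{i}" for i in range(10)],
                "gene": ["GENE_A"] * 2 + ["GENE_B"] * 2 + ["GENE_C"] * 2 + ["NO_SITE"] * 4,
                "is_control": [False] * 6 + [True] * 4,
            }
        )
    )


@pytest.fixture(scope="session")
def ko_screen() -> sf.SimScreen:
    """A small knockout dropout screen reused across scoring/benchmark tests."""
    cfg = sf.SimConfig(n_genes=200, sgrnas_per_gene=4, n_controls=200, seed=42)
    return sf.simulate_screen(cfg)


@pytest.fixture(scope="session")
def ko_lfc(ko_screen) -> pd.Series:
    norm = sf.lognorm(ko_screen.counts)
    lfc = sf.log_fold_change(norm, [("dropout_rep1", "pDNA"), ("dropout_rep2", "pDNA")])
    return sf.average_replicates(lfc, {"avg": list(lfc.lfc.columns)}).column("avg")


@pytest.fixture(scope="session")
def ko_gene_sets(ko_screen):
    tg = ko_screen.truth.genes
    ess = sf.GeneSet.from_iterable(
        "essential", tg.gene[tg.gene_class == "essential"], role="essential"
    )
    ness = sf.GeneSet.from_iterable(
        "nonessential", tg.gene[tg.gene_class == "nonessential"], role="nonessential"
    )
    return ess, ness
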