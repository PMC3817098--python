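import numpy as np
import pytest

import vqtlscan as v


@pytest.fixture
def tiny_genotypes() -> v.GenotypePanel:
    """3 markers x 2 segregants, with one missing call."""
    return v.GenotypePanel(
        segregant_ids=["s1", "s2"],
        marker_ids=["m1", "m2", "m3"],
        marker_chrom=np.array(["chr1", "chr1", "chr2"], dtype=object),
        marker_pos=np.array([100, 200, 100]),
        calls=np.array([[0.0, 1.0, 0.0], [1.0, 1.0, np.nan]]),
    )


@pytest.fixture
def small_panels():
    """A 20-segregant, 2-chromosome panel with one planted additive locus."""
    cfg = v.SimConfig(
        n_segregants=20,
        chrom_lengths={"chr1": 82_000, "chr2": 82_000},
        noise_sd=1.0,
        seed=3,
        architectures=[v.Architecture("trans_additive", [5], effect=3.0)],
        n_null_phenotypes=4,
    )
    g = v.simulate_genotypes(cfg)
    panels, truth = v.simulate_expression(g, cfg)
    return g, panels, truth


@pytest.fixture
def study_109():
    """Study-shaped small genome: 109 segregants, ~200 markers, both treatments."""
    cfg = v.SimConfig(
        n_segregants=109,
        chrom_lengths={"chr1": 410_000, "chr2": 410_000},
        noise_sd=1.0,
        seed=17,
        architectures=[
            v.Architecture("cis_additive", [10], effect=2.0),
            v.Architecture("trans_additive", [150], effect=2.0),
            v.Architecture("and_epistasis", [20, 160], effect=2.0),
            v.Architecture("direct_vqtl", [60], effect=2.0),
        ],
        n_null_phenotypes=6,
    )
    g = v.simulate_genotypes(cfg)
    panels, truth = v.simulate_expression(g, cfg)
    return g, panels, truth


@pytest.fixture
def toy_gff(tmp_path):
    path = tmp_path / "genes.gff3"
    path.write_text(
        "##gff-version 3\n"
        "chr1\tsrc\tgene\t5000\t8000\t.\t+\t.\tID=gene1;Name=GENA\n"
        "chr1\tsrc\tgene\t25000\t30000\t.\t-\t.\tID=gene2;Name=GENB\n"
    )
    return path
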