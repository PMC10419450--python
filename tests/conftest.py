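import numpy as np
import pytest

import peachgs as pg


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """The 'tiny' fixture preset, persisted once per session."""
    out = tmp_path_factory.mktemp("tiny")
    g, pheno, arch, gff = pg.make_fixture_dataset("tiny", out)
    return {"g": g, "pheno": pheno, "arch": arch, "gff": gff, "dir": out}


@pytest.fixture(scope="session")
def small_panel():
    """A 150 x 600 simulated panel with one oligogenic quantitative trait."""
    cfg = pg.SimConfig(n_samples=150, n_chrom=3, markers_per_chrom=200,
                       ld_rho=0.7, n_subpops=2, fst_target=0.1,
                       chrom_length_bp=5_000_000, seed=21)
    g = pg.simulate_genotypes(cfg)
    arch = pg.simulate_architecture(
        g, [{"name": "q1", "n_qtns": 4, "h2": 0.7}], seed=22)
    pheno = pg.simulate_phenotypes(g, arch, seed=23)
    y = pg.normalize_traits(pheno).values["q1"].to_numpy(dtype=float)
    K = pg.genomic_kinship(g, "zhang")
    X = np.column_stack([np.ones(g.n_samples), pg.pca_covariates(g, 3)])
    return {"cfg": cfg, "g": g, "arch": arch, "pheno": pheno,
            "y": y, "K": K, "X": X}
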