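import numpy as np
import pytest

import clonegs as cg
from clonegs.genotypes import GenotypeMatrix, from_dosages


@pytest.fixture
def tiny_genotypes():
    """3 clones x 4 markers, no missing, known dosages (major-allele counts)."""
    dos = np.array([[2, 1, 0, 1],
                    [1, 1, 2, 2],
                    [0, 1, 1, 2]], dtype=float)
    return from_dosages(["c1", "c2", "c3"], ["m1", "m2", "m3", "m4"], dos,
                        orient_major=False)


@pytest.fixture
def half_freq_matrix():
    """Single marker at p=0.5 with all three genotype classes present."""
    return GenotypeMatrix(np.array(["a", "b", "c", "d"]), np.array(["m"]),
                          np.array([[2.0], [1.0], [1.0], [0.0]]),
                          np.array([0.5]))


@pytest.fixture(scope="session")
def small_panel():
    """Simulated 150-clone panel with trials, shared across tests."""
    cfg = cg.SimConfig(n_clones=150, m_markers=400, n_location_years=5,
                       n_reps=2, incidence_rate=0.8, profile="FRY_like",
                       seed=314)
    g, true, trials, manifest = cg.simulate_dataset(cfg)
    return {"cfg": cfg, "g": g, "true": true, "trials": trials,
            "manifest": manifest}


def subset_kinship(mat, idx, ids):
    """Principal submatrix of a relationship matrix, re-conditioned."""
    from clonegs.kinship import RelationshipMatrix, condition_psd

    return condition_psd(RelationshipMatrix(
        mat.kind, mat.values[np.ix_(idx, idx)], np.asarray(ids),
        mat.scaling_constant))


@pytest.fixture(scope="session")
def panel_cvdata(small_panel):
    """Stage-one + kinships for the shared panel, ready for CV."""
    from clonegs.bayes import McmcConfig
    from clonegs.crossval import CVData
    from clonegs.genotypes import MarkerDesigns

    g = small_panel["g"]
    fit1 = cg.fit_stage1(small_panel["trials"], "fry_tha")
    rec = cg.deregress(fit1)
    des = cg.build_designs(cg.impute_mean(g))
    ids = rec["clone"].to_numpy()
    idx = np.array([np.flatnonzero(g.clone_ids == c)[0] for c in ids])
    kin = {
        "additive": subset_kinship(cg.additive_G(des), idx, ids),
        "dom_classical": subset_kinship(cg.dominance_classical(des), idx, ids),
        "dom_genotypic": subset_kinship(cg.dominance_genotypic(des), idx, ids),
        "gaussian_kernel": subset_kinship(cg.gaussian_kernel(cg.impute_mean(g)),
                                          idx, ids),
    }
    sub_des = MarkerDesigns(des.Z_add[idx], des.H_classical[idx],
                            des.H_genotypic[idx], des.p, ids, des.coding_note)
    return CVData(ids, rec["dblup"].to_numpy(), rec["blup"].to_numpy(),
                  kin, sub_des,
                  McmcConfig(n_iter=800, burn_in=200, thin=4, pi=0.95))
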