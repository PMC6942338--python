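import numpy as np
import pandas as pd
import pytest

from snparray import calling, simulate


@pytest.fixture(scope="session")
def sim_config():
    return simulate.SimConfig(n_snps=120, n_samples_per_pop=80, seed=1)


@pytest.fixture(scope="session")
def truth(sim_config):
    return simulate.gen_genotype_truth(sim_config)


@pytest.fixture(scope="session")
def intensities(truth, sim_config):
    return simulate.gen_intensity_data(truth, sim_config)


@pytest.fixture(scope="session")
def contrast_size(intensities):
    sig_a, sig_b = intensities
    contrast, size = calling.transform_intensities(
        sig_a.to_numpy(), sig_b.to_numpy()
    )
    idx, cols = sig_a.index, sig_a.columns
    return (
        pd.DataFrame(contrast, index=idx, columns=cols),
        pd.DataFrame(size, index=idx, columns=cols),
    )


@pytest.fixture(scope="session")
def called(contrast_size):
    """(calls, confidences, diagnostics) for the session dataset."""
    contrast, size = contrast_size
    return calling.call_genotypes(contrast, size)


@pytest.fixture(scope="session")
def candidates_probesets(sim_config):
    return simulate.gen_candidates(sim_config)


def make_transcript_table(candidates, probesets):
    """Transcript ranking inputs derived from a probeset table."""
    from snparray import design

    merged = probesets.merge(
        candidates[["snp_id", "transcript_id"]], on="snp_id", how="left"
    )
    grp = merged.groupby("transcript_id")
    tr = pd.DataFrame(
        {
            "transcript_id": grp.size().index.to_numpy(),
            "hit_category": grp["n_scaffold_hits_v05"]
            .mean()
            .map(design.hit_category)
            .to_numpy(),
            "n_snps": grp["snp_id"].nunique().to_numpy(),
        }
    )
    tr["confidence_score"] = np.nan
    return tr
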