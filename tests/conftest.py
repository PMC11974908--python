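import warnings

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from parstoich import quantify
from parstoich.io_model import MixPoint, PeptidePair, ProteinRecord
from parstoich.simulate import DEFAULT_MIX_POINTS, SimConfig, simulate_experiment


def make_pair(
    sequence="ELVISK",
    protein_ids=("P1",),
    mix_id="1:2000",
    replicate_id="R1",
    light_area=1000.0,
    heavy_area=10.0,
    light_sn=50.0,
    heavy_sn=50.0,
):
    return PeptidePair(
        sequence=sequence,
        protein_ids=frozenset(protein_ids),
        mix_id=mix_id,
        replicate_id=replicate_id,
        light_area=light_area,
        heavy_area=heavy_area,
        light_sn=light_sn,
        heavy_sn=heavy_sn,
    )


@pytest.fixture
def mix_points():
    return list(DEFAULT_MIX_POINTS)


@pytest.fixture
def small_records():
    return [
        ProteinRecord(id="P1", sequence="MKPAKRCDEFGHIK"),
        ProteinRecord(id="P2", sequence="AAAKWWWKYYY"),
    ]


@pytest.fixture(scope="session")
def noisy_run():
    """One simulated two-replicate experiment at the default study conditions,
    quantified end to end. Session-scoped: several tests read from it."""
    cfg = SimConfig(n_proteins=200, ratio_noise_cv=0.2, seed=0)
    tables, truth, records = simulate_experiment(
        cfg, DEFAULT_MIX_POINTS, n_replicates=2
    )
    reference = {r.id for r in records}
    estimates_by_rep = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for rep, pairs in tables.items():
            retained, _ = quantify.filter_peptides(
                pairs, reference, protein_records=records, sites=[]
            )
            estimates_by_rep[rep] = quantify.estimate_stoichiometries(
                retained, DEFAULT_MIX_POINTS, rep
            )
        merged, overlap, r = quantify.merge_replicates(estimates_by_rep)
    return {
        "config": cfg,
        "tables": tables,
        "truth": truth,
        "records": records,
        "estimates_by_rep": estimates_by_rep,
        "merged": merged,
        "overlap": overlap,
        "r": r,
    }
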