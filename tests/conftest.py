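import numpy as np
import pytest

from festkit.model import AnalysisParams, ClonotypeRecord, Condition, WellSample
from festkit.simulate import SimulationConfig, generate_study


@pytest.fixture
def params():
    return AnalysisParams()


def make_well(counts, condition=Condition.S2S, replicate=1, participant="P1",
              batch="batch1", nonproductive=()):
    """Build a well from {cdr3: templates}; keys in ``nonproductive`` are
    flagged non-productive."""
    records = [
        ClonotypeRecord(cdr3_aa=k, templates=v, productive=k not in set(nonproductive))
        for k, v in counts.items()
    ]
    return WellSample(participant=participant, condition=condition,
                      replicate=replicate, assay_batch=batch, records=records)


def make_batch_wells(freq_design, depth=100_000, participant="P1", batch="batch1"):
    """Wells for one batch from a design {condition: [{cdr3: frequency}]}.

    Frequencies are converted to template counts at ``depth``; a filler
    clone absorbs the remaining mass so totals are exact.
    """
    wells = []
    for condition, replicates in freq_design.items():
        for rep, freqs in enumerate(replicates, start=1):
            counts = {k: round(f * depth) for k, f in freqs.items() if f > 0}
            filler = depth - sum(counts.values())
            if filler > 0:
                counts["CFILLERAAAF"] = filler
            wells.append(make_well(counts, condition=condition, replicate=rep,
                                   participant=participant, batch=batch))
    return wells


@pytest.fixture(scope="session")
def small_study():
    """A small, fast synthetic study with a strong designed signal."""
    cfg = SimulationConfig(
        seed=42, n_background_clones=300, n_mono_s2s=20,
        cross_condition_sets=(("HKU1",), ("HKU1", "NL63")),
        n_mono_ccc={"NL63": 4, "229E": 3, "OC43": 3, "HKU1": 5},
        depth=50_000,
    )
    wells, manifest, truth = generate_study(cfg)
    return cfg, wells, manifest, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260920)
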