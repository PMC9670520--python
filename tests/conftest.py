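import numpy as np
import pytest

from bdvp.synthetic import SimConfig, simulate_cohort
from bdvp.variant_store import CarrierMatrix, SampleRecord, SampleSheet, VariantKey

TINY_SIM = SimConfig(
    n_case=20,
    n_bd_only=25,
    n_control=12,
    n_genes=40,
    n_background=300,
    n_signal_per_stratum={"coding": 3, "noncoding": 3, "intergenic": 3},
    n_signal_genes_per_stratum=2,
    signal_carrier_range=(3, 5),
    n_val_case=10,
    n_val_bd_only=6,
    contig_length=400_000,
    seed=11,
)


@pytest.fixture(scope="session")
def tiny_cohort():
    """A small simulated discovery cohort shared across tests."""
    return simulate_cohort(TINY_SIM)


def make_cohort(carrier: np.ndarray, groups: list[str], families: list[str] | None = None,
                roles: list[str] | None = None) -> tuple[CarrierMatrix, SampleSheet]:
    """Hand-build a cohort from a 0/1 array (samples x variants) and groups."""
    carrier = np.asarray(carrier, dtype=np.uint8)
    n, m = carrier.shape
    families = families or [f"F{i}" for i in range(n)]
    roles = roles or [
        "parent" if g == "CONTROL" else "proband" for g in groups
    ]
    sheet = SampleSheet(
        SampleRecord(f"S{i}", families[i], groups[i], roles[i]) for i in range(n)
    )
    variants = [VariantKey("chr1", 100 + j, "A", "T") for j in range(m)]
    return CarrierMatrix(variants, sheet.sample_ids, carrier), sheet


def random_cohort(rng: np.random.Generator, max_samples: int = 30, max_variants: int = 200):
    """A random cohort with random group/family structure (for oracle tests)."""
    n = int(rng.integers(6, max_samples + 1))
    m = int(rng.integers(1, max_variants + 1))
    groups = rng.choice(["BD_CANCER", "BD_ONLY", "CONTROL"], size=n, p=[0.5, 0.3, 0.2])
    while not (groups == "BD_CANCER").any():
        groups = rng.choice(["BD_CANCER", "BD_ONLY", "CONTROL"], size=n, p=[0.5, 0.3, 0.2])
    n_fam = int(rng.integers(1, n + 1))
    families = [f"F{rng.integers(n_fam)}" for _ in range(n)]
    roles = [
        ("parent" if rng.random() < 0.5 else "sibling") if g == "CONTROL"
        else ("proband" if rng.random() < 0.8 else "sibling")
        for g in groups
    ]
    # the recurrence filter requires at least one eligible case proband
    first_case = int(np.flatnonzero(groups == "BD_CANCER")[0])
    roles[first_case] = "proband"
    carrier = (rng.random((n, m)) < rng.uniform(0.02, 0.5)).astype(np.uint8)
    return make_cohort(carrier, list(groups), families, roles)
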