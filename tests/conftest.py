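import numpy as np
import pandas as pd
import pytest

from varbatch.core import KIT_OF_CENTER, MISSING, CallMatrix
from varbatch.simdata import SimConfig, simulate_dataset


def make_calls(
    gt: np.ndarray,
    depth: int = 30,
    vqslod: float = 5.0,
    refs: list[str] | None = None,
    alts: list[str] | None = None,
    chrom: str = "1",
    spacing: int = 1000,
) -> CallMatrix:
    """CallMatrix with clean reads consistent with the given dosage matrix."""
    gt = np.asarray(gt, dtype=np.int8)
    m, n = gt.shape
    frac = np.select([gt == 0, gt == 1, gt == 2], [0.0, 0.5, 1.0], default=0.0)
    ad_alt = np.round(depth * frac).astype(np.int32)
    ad_ref = (depth - ad_alt).astype(np.int32)
    dp = np.full((m, n), depth, dtype=np.int32)
    gq = np.where(gt == MISSING, MISSING, 99).astype(np.int16)
    ad_alt[gt == MISSING] = 0
    ad_ref[gt == MISSING] = 0
    dp[gt == MISSING] = 0
    sites = pd.DataFrame(
        {
            "chrom": [chrom] * m,
            "pos": (np.arange(m) + 1) * spacing,
            "ref": refs if refs is not None else ["A"] * m,
            "alt": alts if alts is not None else ["G"] * m,
            "vqslod": [vqslod] * m,
        }
    )
    return CallMatrix(
        sites=sites,
        samples=[f"S{j:04d}" for j in range(n)],
        gt=gt,
        ad_ref=ad_ref,
        ad_alt=ad_alt,
        dp=dp,
        gq=gq,
    )


def make_samples(
    centers: list[str],
    phenotypes: list[str] | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    rng = rng or np.random.default_rng(0)
    n = len(centers)
    if phenotypes is None:
        phenotypes = rng.choice(["case", "control"], size=n).tolist()
    return pd.DataFrame(
        {
            "sample_id": [f"S{j:04d}" for j in range(n)],
            "center": centers,
            "kit": [KIT_OF_CENTER.get(c, "KitB") for c in centers],
            "sex": rng.choice(["M", "F"], size=n),
            "phenotype": phenotypes,
            "apoe_cov": np.zeros(n, dtype=int),
            "age": np.full(n, 75.0),
        }
    )


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small simulated cohort shared across read-only tests."""
    cfg = SimConfig(
        n_per_center=(120, 90, 60),
        n_variants=150,
        n_causal=2,
        n_biased_causal=1,
        n_biased_null=2,
        seed=7,
    )
    truth, samples, calls = simulate_dataset(cfg)
    return cfg, truth, samples, calls
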