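"""Shared setup for the numbered analysis drivers.

Every driver regenerates the same synthetic cortex deterministically from
SEED, so the scripts can be run independently and in any order.
"""

from functools import lru_cache
from pathlib import Path

import transcortex as tx

SEED = 0
DENSITY = 0.10
RESULTS = Path(__file__).resolve().parent.parent / "results" / "analysis"


def outdir() -> Path:
    RESULTS.mkdir(parents=True, exist_ok=True)
    return RESULTS


@lru_cache(maxsize=1)
def dataset() -> tx.SyntheticDataset:
    return tx.simulate_dataset(tx.fullscale_config(seed=SEED))


@lru_cache(maxsize=1)
def regional():
    from transcortex.pipeline import map_expression

    return map_expression(dataset())


@lru_cache(maxsize=1)
def networks():
    ds = dataset()
    reg, _ = regional()
    scn = tx.pearson_network(ds.thickness, kind="SCN")
    tbn = tx.coexpression_network(reg.values, kind="TBN")
    hse = tx.hse_gene_set()
    present = [g for g in hse.genes if g in reg.values.columns]
    hse_net = tx.coexpression_network(reg.values[present], kind="HSE")
    return scn, tbn, hse_net
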