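import numpy as np
import pandas as pd
import pytest

from boundary_srna.annotation import SENSE, TSS, BoundaryRegion
from boundary_srna.pipeline import run_pipeline
from boundary_srna.simulate import SimConfig, simulate_dataset, truth_evaluation

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return bytes(_BASES[rng.integers(0, 4, size=length)]).decode()


def make_region(
    sequence: str,
    gene_id: str = "G1",
    anchor: str = TSS,
    region_strand: str = SENSE,
    chromosome: str = "Chr1",
    start: int = 0,
    anchor_offset: int | None = None,
    seq_is_forward: bool = True,
) -> BoundaryRegion:
    L = len(sequence)
    return BoundaryRegion(
        gene_id=gene_id,
        anchor=anchor,
        region_strand=region_strand,
        chromosome=chromosome,
        start=start,
        end=start + L,
        anchor_offset=L // 2 if anchor_offset is None else anchor_offset,
        sequence=sequence,
        seq_is_forward=seq_is_forward,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20_240_101)


@pytest.fixture(scope="session")
def default_dataset(tmp_path_factory):
    """The default synthetic world (200 genes, 20% planted, 20x), seed 1,
    run once through the whole pipeline and scored against its truth."""
    root = tmp_path_factory.mktemp("default_dataset")
    dataset = simulate_dataset(SimConfig(seed=1), root)
    result = run_pipeline(root)
    truth = pd.read_csv(dataset.truth_tsv, sep="\t")
    truth["suppressed"] = truth["suppressed"].fillna("")
    metrics = truth_evaluation(result.catalog, truth)
    return {"dataset": dataset, "result": result, "truth": truth, "metrics": metrics}
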