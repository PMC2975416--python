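import pytest

from protstab import (
    Dataset,
    GeneratorConfig,
    MutationInstance,
    from_records,
    generate,
    load_registry,
)
from dataclasses import replace


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture(scope="session")
def small_dataset(registry):
    """Small planted-signal dataset for fast model/selection tests."""
    cfg = replace(
        GeneratorConfig(),
        n_instances=300,
        n_proteins=10,
        seq_length=60,
        noise_sd=0.15,
        seed=7,
    )
    return generate(cfg, registry)


@pytest.fixture()
def toy_instance():
    return MutationInstance(
        protein_id="p1",
        sequence="ACDEFGHIKLMNPQRSTVWY",
        position=6,
        wt_residue="G",
        mut_residue="S",
        ph=7.0,
        ddg=-1.2,
    ).with_label()


def make_dataset(rows):
    """Helper: build a Dataset from (pid, seq, pos, wt, mut, ph, ddg) tuples."""
    return from_records(
        [
            MutationInstance(
                protein_id=pid,
                sequence=seq,
                position=pos,
                wt_residue=wt,
                mut_residue=mut,
                ph=ph,
                ddg=ddg,
            )
            for pid, seq, pos, wt, mut, ph, ddg in rows
        ]
    )
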