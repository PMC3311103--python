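import pytest

import methylseg as ms


def make_amplicon(seq, amp_id="a", chrom="synthetic", start=0):
    return ms.AmpliconRecord(
        id=amp_id, chrom=chrom, start=start, end=start + len(seq), sequence=seq
    )


@pytest.fixture(scope="session")
def strong_dataset():
    """Strong planted signal, 2 cell types: blocks alternate susceptibility
    and susceptible blocks carry embedded 6-mer copies."""
    spec = ms.SyntheticSpec.strong_signal(seed=11, n_amplicons=20)
    amplicons, records, truth = ms.generate(spec)
    return ms.assemble_dataset(amplicons, records), truth


@pytest.fixture(scope="session")
def null_dataset():
    """Zero effect sizes: site labels are coin flips, independent of sequence."""
    spec = ms.SyntheticSpec.null(seed=11, n_amplicons=30, n_cell_types=1)
    amplicons, records, truth = ms.generate(spec)
    return ms.assemble_dataset(amplicons, records), truth
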