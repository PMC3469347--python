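import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from scaffold_eval.io_formats import AlignmentRecord
from scaffold_eval.synthetic import SimParams, emit_alignments, simulate


def make_aln(q, s, pident=100.0, length=200, sstart=1, send=None,
             evalue=1e-50, bitscore=300.0, units="nt", **kw):
    """Compact alignment-row factory for tests."""
    if send is None:
        send = sstart + length - 1
    defaults = dict(
        qseqid=q, sseqid=s, pident=pident, aln_len=length, mismatch=0,
        gapopen=0, qstart=1, qend=length, sstart=sstart, send=send,
        evalue=evalue, bitscore=bitscore, subject_units=units,
    )
    defaults.update(kw)
    return AlignmentRecord(**defaults)


@pytest.fixture(scope="session")
def noise_free_world():
    truth = simulate(SimParams.noise_free(seed=7))
    return truth, emit_alignments(truth)


@pytest.fixture(scope="session")
def noisy_world():
    truth = simulate(SimParams(divergence_my=40.0, seed=11))
    return truth, emit_alignments(truth)
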