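import textwrap

import pytest

from taxonlines.alignments_io import MarkerAlignment


def make_alignment(seqs, marker="toy", coding=True, ids=None):
    ids = ids or [f"s{i}" for i in range(len(seqs))]
    return MarkerAlignment(marker_name=marker, samples=tuple(ids),
                           sequences=tuple(seqs), coding=coding)


@pytest.fixture
def write_fasta(tmp_path):
    def _write(records, name="aln.fasta"):
        path = tmp_path / name
        path.write_text("".join(f">{sid}\n{seq}\n" for sid, seq in records))
        return path
    return _write


@pytest.fixture
def write_metadata(tmp_path):
    def _write(rows, name="meta.csv"):
        path = tmp_path / name
        lines = ["sample_id,population,voucher,sex"]
        lines += [",".join(r) for r in rows]
        path.write_text("\n".join(lines) + "\n")
        return path
    return _write
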