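import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper module

from sgsautosnp.alignment_io import AlignedRead, merge_sorted
from sgsautosnp.simulate import simulate_dataset, write_reference_fasta, write_sam


def make_read(
    seq,
    start=0,
    cultivar="Drysdale",
    contig="c1",
    read_id="r1",
    strand="+",
    proper=True,
):
    return AlignedRead(
        read_id=read_id,
        cultivar=cultivar,
        contig=contig,
        start=start,
        length=len(seq),
        strand=strand,
        sequence=seq,
        is_proper_pair=proper,
    )


@pytest.fixture(scope="session")
def small_dataset():
    """2 contigs x 3 kb, 4 cultivars, 30 planted SNPs, error-free depth 8."""
    return simulate_dataset(
        n_contigs=2, length=3000, n_snps=30, coverage=8.0, error_rate=0.0, seed=11
    )


@pytest.fixture(scope="session")
def small_dataset_merged(small_dataset):
    ds = small_dataset
    return list(
        merge_sorted(
            [ds.reads[c] for c in ds.cultivars], contig_order=list(ds.reference)
        )
    )


@pytest.fixture
def on_disk_dataset(tmp_path, small_dataset):
    """The small dataset written out as FASTA + per-cultivar SAM files."""
    ds = small_dataset
    ref_path = tmp_path / "reference.fa"
    write_reference_fasta(ds.reference, str(ref_path))
    lengths = {name: len(seq) for name, seq in ds.reference.items()}
    sam_paths = {}
    for cultivar in ds.cultivars:
        path = tmp_path / f"{cultivar}.sam"
        write_sam(ds.reads[cultivar], lengths, str(path))
        sam_paths[cultivar] = path
    manifest = tmp_path / "manifest.tsv"
    manifest.write_text(
        "".join(f"{c}\t{sam_paths[c]}\n" for c in ds.cultivars)
    )
    return {
        "dataset": ds,
        "reference": ref_path,
        "sams": sam_paths,
        "manifest": manifest,
        "dir": tmp_path,
    }
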