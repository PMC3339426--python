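import numpy as np
import pandas as pd
import pytest

from xhyb.io import SequenceSet, TwoColorArray


@pytest.fixture
def small_fasta(tmp_path):
    path = tmp_path / "seqs.fasta"
    path.write_text(">p1\nACGT\n>p2 some description\nGGCCTTAA\n")
    return path


@pytest.fixture
def random_sequences():
    rng = np.random.default_rng(42)
    records = []
    for i in range(50):
        seq = "".join(rng.choice(list("ACGT"), size=int(rng.integers(20, 80))))
        records.append((f"s{i}", f"desc {i}", seq))
    return SequenceSet(records, alphabet="nucleotide")


@pytest.fixture
def hit_rows():
    return pd.DataFrame(
        [("t1", "p1", 85.0, 120, 1e-30, 200.0),
         ("t2", "p1", 80.0, 100, 1e-20, 150.0),
         ("t3", "p2", 79.9, 500, 1e-40, 400.0),
         ("t4", "p2", 95.0, 90, 1e-10, 80.0),
         ("t1", "p3", 92.0, 300, 1e-50, 500.0)],
        columns=["query_id", "subject_id", "percent_identity",
                 "alignment_length", "evalue", "bitscore"])


def make_array(n_spots=20, seed=0, flags=None, array_id="arr1",
               dye_orientation="treatment_in_ch1"):
    rng = np.random.default_rng(seed)
    sig1 = 2.0 ** rng.uniform(7, 13, n_spots)
    sig2 = 2.0 ** rng.uniform(7, 13, n_spots)
    bg = rng.normal(100, 10, (2, n_spots)).clip(min=0)
    spots = pd.DataFrame({
        "probe_id": [f"P{i:04d}" for i in range(n_spots)],
        "block": (np.arange(n_spots) % 4) + 1,
        "row": np.arange(n_spots) // 4 + 1,
        "column": np.arange(n_spots) % 4 + 1,
        "fg_ch1": sig1 + bg[0], "bg_ch1": bg[0],
        "fg_ch2": sig2 + bg[1], "bg_ch2": bg[1],
        "flag": flags if flags is not None else np.zeros(n_spots, dtype=int),
    })
    # make (block,row,column) unique
    spots["row"] = np.arange(n_spots)
    return TwoColorArray(spots=spots, array_id=array_id,
                         dye_orientation=dye_orientation)


@pytest.fixture
def tiny_array():
    return make_array(n_spots=16, seed=1)
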