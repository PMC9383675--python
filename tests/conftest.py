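import json

import numpy as np
import pytest

from genomewaves.sequence_io import BASES
from genomewaves.synthetic import RandomSpec, random_nucleotides, write_fasta


@pytest.fixture
def rng():
    return np.random.default_rng(20221)


@pytest.fixture
def fasta_factory(tmp_path):
    """Write a synthetic multi-record FASTA plus a manifest of its contents."""

    def make(n_records, length=120, seed=7, path_name="synthetic.fasta"):
        path = tmp_path / path_name
        manifest = {}
        with open(path, "w") as fh:
            for i in range(n_records):
                spec = RandomSpec(length=length, seed=seed + i, weights=(0.25,) * 4)
                seq = random_nucleotides(spec, seq_id=f"rec{i}")
                manifest[seq.id] = seq.symbols
                fh.write(f">{seq.id}\n")
                for j in range(0, length, 60):
                    fh.write(seq.symbols[j : j + 60] + "\n")
        (tmp_path / "manifest.json").write_text(json.dumps(manifest))
        return path, manifest

    return make


@pytest.fixture
def tiny_fasta(tmp_path):
    """Four-base record whose A-projection is the worked example [1,0,1,1]."""
    path = tmp_path / "tiny.fasta"
    path.write_text(">tiny\nATAA\n")
    return path


def random_binary_vector(rng, length, p_one):
    return (rng.random(length) < p_one).astype(np.int8)


__all__ = ["BASES", "random_binary_vector"]
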