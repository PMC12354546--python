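"""Shared fixtures: small trees and alignments built programmatically."""

import numpy as np
import pytest

from cladevol.codon_selection import SENSE_CODONS, CodonModelSpec
from cladevol.seq_prep import CodonAlignment, ProteinAlignment
from cladevol.trees import Chronogram, LabeledTree


@pytest.fixture
def quartet_tree() -> LabeledTree:
    return LabeledTree.from_newick(
        "((A:0.10,B:0.20):0.05,(C:0.15,D:0.10):0.07);"
    )


@pytest.fixture
def quartet_codon_alignment() -> CodonAlignment:
    return CodonAlignment(
        ["A", "B", "C", "D"],
        ["ATGAAACCCGGG", "ATGAAGCCAGGG", "ATGAACCCG---", "ATGAATCCCGGA"],
    )


@pytest.fixture
def uniform_codon_spec() -> CodonModelSpec:
    return CodonModelSpec(
        kappa=2.0,
        omega_by_class=[0.4],
        codon_frequencies=np.full(61, 1 / 61),
    )


@pytest.fixture
def small_protein_alignment() -> ProteinAlignment:
    return ProteinAlignment(
        ["s1", "s2", "s3", "s4"],
        ["MKLVA", "MKLVA", "MRLIA", "MRLIA"],
    )


@pytest.fixture
def balanced_chronogram() -> Chronogram:
    return Chronogram.from_newick(
        "(((a1:60,a2:60):40,(b1:60,b2:60):40):60,(c1:80,c2:80):80);"
    )
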