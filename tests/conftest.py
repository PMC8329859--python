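import random

import pytest
from Bio.Data.CodonTable import standard_dna_table

from cloneforge import DnaSequence, OrfCandidate, generate_fixture, translate

#: one representative codon per amino acid (standard code)
CODON_FOR = {}
for codon, aa in standard_dna_table.forward_table.items():
    CODON_FOR.setdefault(aa, codon)


@pytest.fixture(scope="session")
def cds_with_stop() -> DnaSequence:
    """A clean synthetic 100-codon CDS including its stop codon."""
    return generate_fixture("orf", {"n_codons": 100}, seed=1)


@pytest.fixture(scope="session")
def cds(cds_with_stop) -> DnaSequence:
    return DnaSequence(bases=cds_with_stop.bases[:-3], name="fix_cds")


@pytest.fixture(scope="session")
def protein(cds):
    prot, _ = translate(cds)
    return prot


def orf_candidate_for(protein_residues: str, source_id: str = "cand") -> OrfCandidate:
    """Back-translate a protein into a consistent OrfCandidate."""
    from cloneforge import ProteinSequence

    cds = "".join(CODON_FOR[aa] for aa in protein_residues)
    return OrfCandidate(
        source_id=source_id,
        strand="+",
        start_base=1,
        end_base=len(cds),
        cds=DnaSequence(bases=cds, name=source_id),
        translation=ProteinSequence(residues=protein_residues, name=source_id),
    )


def mutate_protein(residues: str, k: int, seed: int = 0) -> str:
    """Apply exactly k single amino-acid substitutions."""
    rng = random.Random(seed)
    alphabet = sorted(set("ACDEFGHIKLMNPQRSTVWY"))
    out = list(residues)
    for pos in rng.sample(range(len(residues)), k):
        out[pos] = rng.choice([a for a in alphabet if a != out[pos]])
    return "".join(out)
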