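"""Optional network adapter: download records for offline ingestion.

Convenience plumbing only — everything else in this package works on
local files, and nothing here is exercised by the test suite. Given a
UniProt accession this fetches the protein entry (with isoform sequences)
and its cross-referenced nucleotide records, writing plain files that
:mod:`cloneforge.isomatch` can then consume.
"""

from __future__ import annotations

import urllib.request
from pathlib import Path

UNIPROT_FASTA_URL = "https://rest.uniprot.org/uniprotkb/{acc}.fasta?includeIsoform=true"
ENA_EMBL_URL = "https://www.ebi.ac.uk/ena/browser/api/embl/{acc}"


def _download(url: str, dest: Path, timeout: float = 30.0) -> Path:
    with urllib.request.urlopen(url, timeout=timeout) as resp:  # pragma: no cover
        dest.write_bytes(resp.read())
    return dest


def fetch_uniprot_isoforms(accession: str, out_dir) -> Path:  # pragma: no cover
    """Download all isoform sequences for a UniProt accession (FASTA)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    return _download(
        UNIPROT_FASTA_URL.format(acc=accession),
        out_dir / f"{accession}_isoforms.fasta",
    )


def fetch_nucleotide_record(accession: str, out_dir) -> Path:  # pragma: no cover
    """Download a cross-referenced nucleotide record (EMBL flat file)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    return _download(
        ENA_EMBL_URL.format(acc=accession), out_dir / f"{accession}.embl"
    )
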