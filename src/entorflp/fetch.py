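"""Optional retrieval of reference sequences from public archives.

The assay was developed against deposited ITS reference accessions (for the
four *Entoloma* reference taxa: LN088049, LN088033, LN088042, LN088067).
This helper fetches such records from ENA when network access is available;
nothing else in the package depends on it, and the test suite runs entirely
on synthetic fixtures.
"""

from __future__ import annotations

import urllib.request

from .iupac import NucleotideSequence

__all__ = ["fetch_accession", "ENA_FASTA_URL"]

ENA_FASTA_URL = "https://www.ebi.ac.uk/ena/browser/api/fasta/{accession}"


def fetch_accession(accession: str, timeout: float = 30.0) -> NucleotideSequence:
    """Download one nucleotide record from ENA as a validated sequence."""
    url = ENA_FASTA_URL.format(accession=accession)
    with urllib.request.urlopen(url, timeout=timeout) as resp:
        text = resp.read().decode()
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if not lines or not lines[0].startswith(">"):
        raise ValueError(f"{accession}: unexpected response from ENA")
    header = lines[0][1:]
    parts = header.split(None, 1)
    return NucleotideSequence(
        id=accession,
        residues="".join(lines[1:]),
        description=parts[1] if len(parts) > 1 else "",
    )
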