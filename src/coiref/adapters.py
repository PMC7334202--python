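"""Optional live-retrieval adapters (untested plumbing).

These helpers fetch records over the network and return the same
:class:`~coiref.records.SeqRecord` objects as the file-based ingest, so the
rest of the pipeline is agnostic to where data came from.  They are thin,
best-effort conveniences: the supported, tested path is local files.  The
``requests`` dependency is imported lazily and is NOT a package requirement.
"""

from __future__ import annotations

from .ingest import SearchTerm, parse_bold_tsv, parse_genbank_flatfile, render_entrez_query
from .records import SeqRecord

NCBI_EUTILS = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils"
BOLD_API = "https://www.boldsystems.org/index.php/API_Public/combined"


def fetch_genbank(term: SearchTerm, email: str, api_key: str | None = None,
                  retmax: int = 10000) -> list[SeqRecord]:
    """Search + fetch GenBank flatfiles for one term via E-utilities."""
    import requests  # optional dependency

    params = {
        "db": "nucleotide",
        "term": render_entrez_query(term),
        "retmax": retmax,
        "email": email,
    }
    if api_key:
        params["api_key"] = api_key
    ids = requests.get(f"{NCBI_EUTILS}/esearch.fcgi", params=params, timeout=120)
    ids.raise_for_status()
    id_list = [
        line.split("<Id>")[1].split("</Id>")[0]
        for line in ids.text.splitlines()
        if "<Id>" in line
    ]
    if not id_list:
        return []
    flat = requests.get(
        f"{NCBI_EUTILS}/efetch.fcgi",
        params={"db": "nucleotide", "id": ",".join(id_list), "rettype": "gb",
                "retmode": "text", "email": email},
        timeout=600,
    )
    flat.raise_for_status()
    records, _ = parse_genbank_flatfile(flat.text)
    return records


def fetch_bold(taxon: str) -> list[SeqRecord]:
    """Fetch one taxon's records from the BOLD combined TSV endpoint."""
    import requests  # optional dependency

    resp = requests.get(BOLD_API, params={"taxon": taxon, "format": "tsv"},
                        timeout=600)
    resp.raise_for_status()
    records, _ = parse_bold_tsv(resp.text)
    return records
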