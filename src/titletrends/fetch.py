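"""Optional thin wrapper around NCBI E-utilities efetch.

Downloads raw PubmedArticleSet XML to disk for later parsing with
:func:`titletrends.records.parse_medline_xml`. Network access is required;
nothing in the test suite or pipeline depends on this module.
"""

from __future__ import annotations

import time
import urllib.parse
import urllib.request
from pathlib import Path
from typing import Iterable, Sequence

EFETCH_URL = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
ESEARCH_URL = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/esearch.fcgi"


def efetch_pmids(
    pmids: Sequence[str],
    out_path: str | Path,
    batch_size: int = 200,
    delay_s: float = 0.4,
) -> Path:
    """Fetch citations by PMID and write the raw XML to *out_path*.

    Batches requests and sleeps between them to respect NCBI rate limits.
    """
    out_path = Path(out_path)
    chunks: list[bytes] = []
    for i in range(0, len(pmids), batch_size):
        batch = pmids[i:i + batch_size]
        params = urllib.parse.urlencode(
            {"db": "pubmed", "retmode": "xml", "id": ",".join(batch)}
        )
        with urllib.request.urlopen(f"{EFETCH_URL}?{params}") as resp:
            chunks.append(resp.read())
        if i + batch_size < len(pmids):
            time.sleep(delay_s)
    # keep only the first document header/root; naive concat is fine for
    # single-batch fetches, multi-batch callers should parse per chunk
    if len(chunks) == 1:
        out_path.write_bytes(chunks[0])
    else:
        out_path.parent.mkdir(parents=True, exist_ok=True)
        for j, blob in enumerate(chunks):
            out_path.with_suffix(f".{j:03d}.xml").write_bytes(blob)
    return out_path


def esearch_journal_years(journal: str, year_min: int, year_max: int) -> str:
    """Build the esearch term for one journal and an inclusive year window."""
    return (
        f'"{journal}"[Journal] AND ("{year_min}"[Date - Publication] : '
        f'"{year_max}"[Date - Publication])'
    )
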