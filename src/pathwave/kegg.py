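"""Building KEGG map-coloring URLs from analysis results.

For each significant pathway with a KEGG identifier, a GET URL against
the KEGG pathway viewer is assembled that colors each reaction/protein by
its direction call.  No network access is performed here — the URLs are
returned for the user to open.  Palette (background colors): up = salmon
(#ff8080), down = light blue (#8080ff), no change = light gray (#d0d0d0).
"""

from __future__ import annotations

import logging
import re

from .stats import PathwayResult

logger = logging.getLogger(__name__)

__all__ = ["kegg_color_urls", "COLOR_UP", "COLOR_DOWN", "COLOR_NOCHANGE"]

BASE_URL = "https://www.kegg.jp/kegg-bin/show_pathway"
COLOR_UP = "%23ff8080"
COLOR_DOWN = "%238080ff"
COLOR_NOCHANGE = "%23d0d0d0"
_CALL_COLORS = {"up": COLOR_UP, "down": COLOR_DOWN, "nochange": COLOR_NOCHANGE}

# documented practical GET-length limit for the KEGG viewer
MAX_URL_LENGTH = 2000

_KEGG_ID = re.compile(r"(?:path:)?([a-z]{2,4}\d{5})$")


def _kegg_map_id(pathway_id: str) -> str | None:
    m = _KEGG_ID.search(pathway_id)
    return m.group(1) if m else None


def kegg_color_urls(
    results: list[PathwayResult],
    direction_calls: dict[str, dict[str, str]] | None = None,
    max_url_length: int = MAX_URL_LENGTH,
) -> list[str]:
    """One (or, for long queries, several) coloring URL per pathway.

    ``direction_calls`` maps pathway id -> entity id -> up/down/nochange;
    when omitted, the calls stored on each result are used.  Entities are
    encoded as ``<id>%09<background color>`` query terms; queries longer
    than ``max_url_length`` are split over several URLs.  Pathways whose
    id does not contain a KEGG map identifier are skipped with a warning.
    """
    urls: list[str] = []
    for r in results:
        map_id = _kegg_map_id(r.pathway_id)
        if map_id is None:
            logger.warning("pathway %s has no KEGG map id; skipped", r.pathway_id)
            continue
        calls = (direction_calls or {}).get(r.pathway_id, r.direction_calls)
        terms = [
            f"{entity}%09{_CALL_COLORS[call]}"
            for entity, call in sorted(calls.items())
            if call in _CALL_COLORS
        ]
        if not terms:
            continue
        prefix = f"{BASE_URL}?{map_id}"
        batch: list[str] = []
        for term in terms:
            candidate_len = len(prefix) + sum(len(t) + 1 for t in batch) + len(term) + 1
            if batch and candidate_len > max_url_length:
                urls.append(prefix + "/" + "/".join(batch))
                batch = []
            batch.append(term)
        urls.append(prefix + "/" + "/".join(batch))
    return urls
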