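"""Gene-set over-representation analysis.

One-sided hypergeometric test of each gene set against a query list,
with the quantified genes as background and Benjamini-Hochberg FDR
across the tested sets.  This is the standard stand-in statistic for
curated-ontology enrichment tools whose internal test is not public;
the output metadata labels it as such.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
from scipy.stats import hypergeom

from .destats import bh_fdr
from .matrix import ValidationError

logger = logging.getLogger(__name__)


def read_gmt(path: str | Path) -> dict[str, dict]:
    """Read a GMT file: name <tab> description <tab> member genes."""
    sets: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(f"malformed GMT line: {line[:60]!r}")
            name, description, members = parts[0], parts[1], [g for g in parts[2:] if g]
            if name in sets:
                raise ValidationError(f"duplicate gene-set name: {name}")
            if not members:
                raise ValidationError(f"gene set {name} has no members")
            sets[name] = {"description": description, "members": frozenset(members)}
    return sets


def write_gmt(sets: dict[str, dict], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, entry in sets.items():
            members = sorted(entry["members"])
            fh.write("\t".join([name, entry.get("description", "")] + members) + "\n")


def enrich(
    query,
    sets: dict[str, dict],
    background,
    fdr_alpha: float = 0.05,
    min_set_size: int = 3,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of each set.

    Per set: overlap ``k``, in-background set size ``K``, query size
    ``n``, background size ``N``, p = P(X >= k) for X ~
    Hypergeom(N, K, n), BH ``q`` across tested sets and a significance
    flag (q < ``fdr_alpha``).  Sets whose intersection with the
    background falls below ``min_set_size`` are skipped and logged.
    """
    query = set(query)
    background = set(background)
    offenders = sorted(query - background)
    if offenders:
        raise ValidationError(f"query genes absent from background: {offenders[:10]}")
    N = len(background)
    n = len(query)
    rows = []
    for name, entry in sets.items():
        members = entry["members"] & background
        K = len(members)
        if K < min_set_size:
            logger.info("skipping set %s: only %d members in background", name, K)
            continue
        k = len(members & query)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append({"set": name, "k": k, "K": K, "n": n, "N": N, "p": min(p, 1.0)})
    table = pd.DataFrame(rows, columns=["set", "k", "K", "n", "N", "p"])
    if len(table):
        table["q"] = bh_fdr(table["p"].to_numpy())
        table["significant"] = table["q"] < fdr_alpha
    else:
        table["q"] = []
        table["significant"] = []
    return table
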