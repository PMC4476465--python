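"""Cross-species comparison of diel genes.

Joins a set of Nematostella diel cycle genes (DCGs) against homolog mapping
tables from coral studies, and applies the >=3-fold day/night expression
filter to printed larval count pairs. Two transcribed homolog tables ship
with the package: ``table2.tsv`` (adult coral microarray homolog pairs with
peak times) and ``table3.tsv`` (coral larval day/night read counts).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = [
    "HomologPair",
    "fold_change_filter",
    "overlap_dcgs",
    "load_homolog_table",
    "packaged_table",
]


@dataclass
class HomologPair:
    """A Nematostella gene paired with a coral homolog and day/night counts."""

    nv_gene_id: str
    am_seqindex: str
    annotation: str = ""
    day_count: int = 0
    night_count: int = 0
    direction: str = "none"  # filled by fold_change_filter

    def __post_init__(self) -> None:
        if self.day_count < 0 or self.night_count < 0:
            raise ValueError("counts must be non-negative")


def fold_change_filter(
    pairs: list[HomologPair], threshold: float = 3.0
) -> tuple[list[HomologPair], list[HomologPair]]:
    """Split homolog pairs into day- and night-upregulated at a fold threshold.

    A pair is day-upregulated iff ``day_count >= threshold * night_count``
    with ``day_count > 0`` (a zero night count with positive day count is an
    infinite fold and passes); night-upregulated symmetrically. The
    threshold is inclusive. Pairs with both counts zero are flagged
    ``direction="none"`` and returned in neither list, as are pairs below
    threshold. Each pair's ``direction`` field is set in place.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    day_up: list[HomologPair] = []
    night_up: list[HomologPair] = []
    for p in pairs:
        d, n = p.day_count, p.night_count
        day_ok = d > 0 and d >= threshold * n
        night_ok = n > 0 and n >= threshold * d
        if day_ok and not night_ok:
            p.direction = "day"
            day_up.append(p)
        elif night_ok and not day_ok:
            p.direction = "night"
            night_up.append(p)
        else:
            # both directions qualifying (possible only at threshold <= 1
            # with near-equal counts) means no day/night difference
            p.direction = "none"
    return day_up, night_up


def overlap_dcgs(
    dcgs: pd.Index | list[str], homolog_map: pd.DataFrame
) -> tuple[pd.DataFrame, int]:
    """Inner-join DCG ids against a homolog map keyed by ``nv_gene_id``.

    Returns the joined table (one row per DCG with a homolog) and the
    number of DCGs with no mapping.
    """
    if "nv_gene_id" in homolog_map.columns:
        keyed = homolog_map.set_index(homolog_map["nv_gene_id"].astype(str))
    else:
        keyed = homolog_map
        keyed.index = keyed.index.astype(str)
    ids = pd.Index([str(g) for g in dcgs])
    hit = ids[ids.isin(keyed.index)]
    unmapped = int(len(ids) - len(hit))
    return keyed.loc[hit].reset_index(drop=True), unmapped


def load_homolog_table(path) -> pd.DataFrame:
    """Read a homolog TSV; requires an ``nv_gene_id`` column."""
    df = pd.read_csv(path, sep="\t", dtype={"nv_gene_id": str, "am_seqindex": str})
    if "nv_gene_id" not in df.columns:
        raise ValueError(f"{path}: missing required column 'nv_gene_id'")
    for col in ("day_count", "night_count"):
        if col in df.columns and (df[col] < 0).any():
            raise ValueError(f"{path}: negative values in {col}")
    return df


def packaged_table(name: str) -> pd.DataFrame:
    """Load a homolog table shipped with the package ('table2' or 'table3')."""
    ref = resources.files("dielrhythm.data").joinpath(f"{name}.tsv")
    with resources.as_file(ref) as path:
        return load_homolog_table(path)


def table_pairs(df: pd.DataFrame) -> list[HomologPair]:
    """Convert a homolog table with day/night counts into HomologPair objects."""
    return [
        HomologPair(
            nv_gene_id=str(r["nv_gene_id"]),
            am_seqindex=str(r.get("am_seqindex", "")),
            annotation=str(r.get("annotation", "")),
            day_count=int(r["day_count"]),
            night_count=int(r["night_count"]),
        )
        for _, r in df.iterrows()
    ]
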