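"""Readers and writers for trees, locus tables, clade configs and tracks.

On-disk conventions
-------------------
* Locus trees: one tree per line, ``locus_id<TAB>newick`` (a single
  space also accepted as separator).
* Locus table: TSV with header ``locus_id chrom start end``;
  coordinates 1-based inclusive.
* Clade configuration: YAML naming taxon groups and the
  quadripartitions / bipartitions to score (see ``read_clade_config``).
* Tracks and window results: TSV, missing values written as ``NA``.
* Outlier regions: BED (0-based half-open), converted from the
  internal 1-based inclusive coordinates.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd
import yaml

from .model import (
    Bipartition,
    CladeModel,
    GenomeTable,
    LocusTree,
    OutlierRegion,
    Quadripartition,
    SupportTrack,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_locus_trees",
    "write_locus_trees",
    "read_locus_table",
    "write_locus_table",
    "read_clade_config",
    "read_track",
    "write_track",
    "write_regions_bed",
    "write_window_results",
    "parse_newick",
]


def parse_newick(newick: str) -> dendropy.Tree:
    """Parse a single newick string into an unrooted dendropy tree."""
    tree = dendropy.Tree.get(
        data=newick,
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    tree.is_rooted = False
    return tree


def read_locus_trees(path) -> list[LocusTree]:
    """Read one locus tree per line (``locus_id<TAB>newick``)."""
    out: list[LocusTree] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sep = "\t" if "\t" in line else None
            parts = line.split(sep, 1)
            if len(parts) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 'locus_id<TAB>newick'"
                )
            locus_id, newick = parts[0].strip(), parts[1].strip()
            if locus_id in seen:
                raise ValueError(
                    f"{path}:{lineno}: duplicate locus ID {locus_id!r}"
                )
            seen.add(locus_id)
            try:
                tree = parse_newick(newick)
            except Exception as exc:
                raise ValueError(
                    f"{path}:{lineno}: malformed newick for locus "
                    f"{locus_id!r}: {exc}"
                ) from exc
            out.append(LocusTree(locus_id=locus_id, tree=tree))
    return out


def write_locus_trees(trees: Iterable[LocusTree], path) -> None:
    with open(path, "w") as fh:
        for lt in trees:
            newick = lt.tree.as_string(
                schema="newick",
                suppress_rooting=True,
                unquoted_underscores=True,
            ).strip()
            fh.write(f"{lt.locus_id}\t{newick}\n")


def read_locus_table(path, tree_ids: set[str] | None = None) -> GenomeTable:
    """Read the TSV locus table; rows are returned sorted by
    (chromosome, start), with a logged notice when input was unsorted.

    When ``tree_ids`` is given, loci absent from it produce a warning
    but the rows are kept.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"locus_id": str, "chrom": str, "start": np.int64, "end": np.int64},
    )
    missing_cols = set(GenomeTable.COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"{path}: missing columns {sorted(missing_cols)}")
    table = GenomeTable(df)
    if not df[["chrom", "start"]].equals(table.df[["chrom", "start"]]):
        logger.info("%s: locus table was unsorted; sorted by (chrom, start)", path)
    if tree_ids is not None:
        absent = [i for i in table.locus_ids if i not in tree_ids]
        if absent:
            logger.warning(
                "%s: %d loci have no tree (e.g. %s); rows kept",
                path,
                len(absent),
                absent[:3],
            )
    return table


def write_locus_table(table: GenomeTable, path) -> None:
    table.df.to_csv(path, sep="\t", index=False)


def _as_taxon_set(spec, groups: dict[str, frozenset], what: str) -> frozenset:
    """Resolve a group name, list of group names, or list of taxa."""
    if isinstance(spec, str):
        if spec not in groups:
            raise ValueError(f"{what}: unknown group {spec!r}")
        return groups[spec]
    out: set[str] = set()
    for item in spec:
        if item in groups:
            out |= groups[item]
        else:
            out.add(item)
    return frozenset(out)


def read_clade_config(path) -> CladeModel:
    """Read a YAML clade configuration.

    Layout::

        groups:
          Columbimorphae: [pigeon, mesite, sandgrouse]
          Mirandornithes: [flamingo, grebe]
          ...
        outgroup: [chicken]
        quadripartitions:
          - name: Columbea
            A: Columbimorphae
            B: Mirandornithes
            C: [Passerea]
            D: [NonNeoaves]
        bipartitions:
          - name: Columbea
            X: [Columbimorphae, Mirandornithes]
            Y: [Passerea, NonNeoaves]

    Group references resolve to their taxon sets; bare names inside a
    list that are not group names are taken as taxa. Outgroup taxa are
    appended to the D side of every quadripartition.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    groups: dict[str, frozenset] = {}
    for name, taxa in (raw.get("groups") or {}).items():
        if not taxa:
            raise ValueError(f"clade config: group {name!r} is empty")
        groups[name] = frozenset(taxa)
    outgroup = frozenset(raw.get("outgroup") or ())
    quads = []
    for q in raw.get("quadripartitions") or []:
        name = q["name"]
        parts = [
            _as_taxon_set(q[k], groups, f"quadripartition {name}, side {k}")
            for k in ("A", "B", "C", "D")
        ]
        parts[3] = parts[3] | outgroup
        quads.append(Quadripartition(name, *map(frozenset, parts)))
    bips = []
    for b in raw.get("bipartitions") or []:
        name = b["name"]
        X = _as_taxon_set(b["X"], groups, f"bipartition {name}, side X")
        Y = _as_taxon_set(b["Y"], groups, f"bipartition {name}, side Y")
        bips.append(Bipartition(name, X, Y))
    return CladeModel(
        groups=groups,
        quadripartitions=quads,
        bipartitions=bips,
        outgroup=outgroup,
    )


def write_track(track: SupportTrack, path) -> None:
    """TSV of (locus_id, chrom, start, value); missing written as NA."""
    df = track.table.df.loc[:, ["locus_id", "chrom", "start"]].copy()
    df[track.name] = track.values
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")


def read_track(path, table: GenomeTable) -> SupportTrack:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"locus_id": str})
    value_col = df.columns[-1]
    by_id = dict(zip(df["locus_id"], df[value_col]))
    values = np.array(
        [by_id.get(i, np.nan) for i in table.locus_ids], dtype=float
    )
    return SupportTrack(table=table, values=values, name=value_col)


def write_regions_bed(regions: Sequence[OutlierRegion], path) -> None:
    """Write regions as BED: 0-based half-open, score = min adjusted p."""
    regions = sorted(regions, key=lambda r: (r.chrom, r.start))
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tmin_p_adj\n")
        for i, r in enumerate(regions, start=1):
            fh.write(
                f"{r.chrom}\t{r.start - 1}\t{r.end}\tregion_{i}\t"
                f"{r.min_p_adj:.6g}\n"
            )


def write_window_results(windows: pd.DataFrame, path) -> None:
    windows.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")
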