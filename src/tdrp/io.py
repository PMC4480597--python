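"""Readers and writers for the package's on-disk formats.

Trees are rooted Newick with mandatory branch lengths (substitutions per
site) and internal labels carrying node ids.  Node tables are CSV, one row
per internal node, with s summarised as median and 95 % bounds (expanded
to log-normal draws on read, flagged reconstructed) or supplied as raw
draws in a long-format companion.  Times in files are Myr; rates in
outputs are substitutions/site/year; columns carry unit suffixes.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, List, Optional, Union

import dendropy
import numpy as np
import pandas as pd

from .dataset import (
    CalibrationPrior,
    CospeciationDataset,
    NodeRecord,
    reconstruct_s_samples,
)

__all__ = [
    "read_tree",
    "write_tree",
    "read_node_table",
    "write_node_table",
    "load_dataset",
    "write_manifest",
]

NODE_TABLE_COLUMNS = [
    "node_id",
    "parent_id",
    "s_median",
    "s_lower95",
    "s_upper95",
    "t_median_myr",
    "t_lower95_myr",
    "t_upper95_myr",
]


def read_tree(path: Union[str, Path]) -> dendropy.Tree:
    """Parse a rooted Newick tree; every non-root edge must carry a length."""
    tree = dendropy.Tree.get(
        path=str(path), schema="newick", suppress_internal_node_taxa=True,
        rooting="force-rooted",
    )
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None and nd.edge.length is None:
            who = nd.taxon.label if nd.taxon else (nd.label or "<unnamed clade>")
            raise ValueError(f"missing branch length above {who!r} in {path}")
    return tree


def write_tree(tree: dendropy.Tree, path: Union[str, Path]) -> None:
    Path(path).write_text(
        tree.as_string(
            schema="newick",
            suppress_rooting=True,
            real_value_format_specifier=".17g",
        )
    )


def read_node_table(
    path: Union[str, Path],
    n_s_draws: int = 1000,
    seed=0,
    s_draws_path: Optional[Union[str, Path]] = None,
) -> List[NodeRecord]:
    """Read a node table CSV into NodeRecords.

    Rows with empty t fields become undated records.  If ``s_draws_path``
    (long format: node_id, draw_index, s) is given, those draws are used;
    otherwise draws are reconstructed log-normally from the s summary and
    flagged as reconstructed.
    """
    df = pd.read_csv(path, dtype={"node_id": str, "parent_id": str})
    missing = [c for c in NODE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    draws_by_node: Dict[str, np.ndarray] = {}
    if s_draws_path is not None:
        long = pd.read_csv(s_draws_path, dtype={"node_id": str})
        for nid, grp in long.groupby("node_id"):
            draws_by_node[str(nid)] = grp.sort_values("draw_index")["s"].to_numpy(float)
    rng = np.random.default_rng(seed)
    records = []
    for i, row in df.iterrows():
        rownum = i + 2  # 1-based with header
        nid = str(row.node_id)
        pid = None if pd.isna(row.parent_id) or row.parent_id == "" else str(row.parent_id)
        t_fields = [row.t_median_myr, row.t_lower95_myr, row.t_upper95_myr]
        dated = not any(pd.isna(v) for v in t_fields)
        if any(pd.isna(v) for v in t_fields) and not all(pd.isna(v) for v in t_fields):
            raise ValueError(f"{path} row {rownum}: partial t fields")
        try:
            if nid in draws_by_node:
                s_samples, recon = draws_by_node[nid], False
            else:
                s_samples = reconstruct_s_samples(
                    float(row.s_median), float(row.s_lower95), float(row.s_upper95),
                    n_s_draws, rng,
                )
                recon = True
            calib = (
                CalibrationPrior(float(row.t_median_myr), float(row.t_lower95_myr),
                                 float(row.t_upper95_myr))
                if dated
                else None
            )
        except ValueError as exc:
            raise ValueError(f"{path} row {rownum} (node {nid}): {exc}") from exc
        records.append(
            NodeRecord(node_id=nid, parent_id=pid, s_samples=s_samples,
                       calibration=calib, s_reconstructed=recon)
        )
    return records


def write_node_table(dataset: CospeciationDataset, path: Union[str, Path]) -> None:
    """Summarise a dataset back to the node-table CSV format."""
    rows = []
    for rec in dataset.nodes.values():
        s = rec.s_samples
        row = {
            "node_id": rec.node_id,
            "parent_id": rec.parent_id if rec.parent_id is not None else "",
            "s_median": float(np.median(s)),
            "s_lower95": float(np.percentile(s, 2.5)),
            "s_upper95": float(np.percentile(s, 97.5)),
            "t_median_myr": rec.calibration.median if rec.is_dated else "",
            "t_lower95_myr": rec.calibration.lower95 if rec.is_dated else "",
            "t_upper95_myr": rec.calibration.upper95 if rec.is_dated else "",
        }
        rows.append(row)
    pd.DataFrame(rows, columns=NODE_TABLE_COLUMNS).to_csv(path, index=False)


def load_dataset(
    tree_path: Optional[Union[str, Path]],
    table_path: Union[str, Path],
    n_s_draws: int = 1000,
    seed=0,
    s_draws_path: Optional[Union[str, Path]] = None,
) -> CospeciationDataset:
    records = read_node_table(table_path, n_s_draws=n_s_draws, seed=seed,
                              s_draws_path=s_draws_path)
    tree = read_tree(tree_path) if tree_path is not None else None
    return CospeciationDataset(records, tree=tree)


def write_manifest(path: Union[str, Path], config: dict,
                   input_paths: Dict[str, Union[str, Path]]) -> None:
    """Run manifest: config echo, package version and input checksums."""
    from . import __version__

    checksums = {}
    for name, p in input_paths.items():
        p = Path(p)
        if p.exists():
            checksums[name] = hashlib.sha256(p.read_bytes()).hexdigest()
    Path(path).write_text(
        json.dumps(
            {"config": config, "tdrp_version": __version__, "input_sha256": checksums},
            indent=2, default=str,
        )
    )
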