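"""Catalytic-site signature extraction and tree-annotation export.

Classifies the residues found at normalized positions 68, 102, 199, 246
and 250 as LDH-like or MalDH-like and writes one iTOL-style binary
dataset per position so the calls can be drawn as circles of triangles
on a phylogeny.
"""

from __future__ import annotations

import re
import warnings
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import InputError
from .numbering import AlignParams, ReferenceProfile, build_residue_map, load_reference, residue_at

__all__ = [
    "SIGNATURE_POSITIONS",
    "classify_position",
    "signature_table",
    "export_tree_annotation",
    "parse_tree_annotation",
]

LDH_LIKE = "LDH_like"
MALDH_LIKE = "MalDH_like"
OTHER = "other"
ABSENT = "absent"

SIGNATURE_POSITIONS = (68, 102, 199, 246, 250)

# Per-position residue -> class rules. Position 199 deliberately has no
# MalDH_like entry: only the acidic D/E is a marked class there; the raw
# residue is still exported so "acidic vs not" stays reproducible.
_RULES: dict[int, dict[str, str]] = {
    68: {"H": LDH_LIKE, "D": MALDH_LIKE, "Q": MALDH_LIKE},
    102: {"Q": LDH_LIKE, "R": MALDH_LIKE},
    199: {"D": LDH_LIKE, "E": LDH_LIKE},
    246: {"T": LDH_LIKE, "A": MALDH_LIKE, "S": MALDH_LIKE},
    250: {"I": LDH_LIKE, "P": MALDH_LIKE},
}


def classify_position(position: int, residue: str) -> str:
    """Class label for an observed residue at a signature position."""
    if position not in _RULES:
        raise InputError(
            f"position {position} has no signature rule; supported: "
            f"{sorted(_RULES)}"
        )
    if residue is None:
        return ABSENT
    residue = residue.upper()
    if len(residue) != 1 or not residue.isalpha():
        raise InputError(f"not a one-letter amino acid: {residue!r}")
    return _RULES[position].get(residue, OTHER)


def signature_table(
    sequences: Mapping[str, str] | Iterable[tuple[str, str]],
    positions: Iterable[int] = SIGNATURE_POSITIONS,
    reference: ReferenceProfile | None = None,
    align_params: AlignParams | None = None,
) -> pd.DataFrame:
    """One row per sequence with observed residue and class per position.

    Unmappable sequences are kept (flagged ``mapped=False``) rather than
    dropped, so downstream joins against the tree stay complete.
    """
    positions = tuple(positions)
    for p in positions:
        if p not in _RULES:
            raise InputError(f"unsupported signature position {p}")
    ref = reference or load_reference()
    if isinstance(sequences, Mapping):
        items = list(sequences.items())
    else:
        items = list(sequences)
    rows = []
    for seq_id, seq in items:
        row: dict = {"id": seq_id, "mapped": True, "identity": float("nan")}
        try:
            rmap = build_residue_map(
                seq, ref, align_params=align_params, query_id=seq_id
            )
        except InputError as exc:
            warnings.warn(f"{seq_id}: unmappable ({exc})", stacklevel=2)
            row["mapped"] = False
            for p in positions:
                row[f"aa{p}"] = None
                row[f"class{p}"] = ABSENT
            rows.append(row)
            continue
        row["identity"] = rmap.identity
        for p in positions:
            aa = residue_at(rmap, seq, p)
            row[f"aa{p}"] = aa
            row[f"class{p}"] = classify_position(p, aa) if aa else ABSENT
        rows.append(row)
    return pd.DataFrame(rows).set_index("id")


_CODE = {LDH_LIKE: "1", MALDH_LIKE: "0", OTHER: "-1"}
_LABEL = {v: k for k, v in _CODE.items()}


def _tree_leaf_labels(tree_source: str) -> list[str]:
    import dendropy

    kwargs = {"schema": "newick", "preserve_underscores": True}
    if re.search(r"[();]", tree_source):
        tree = dendropy.Tree.get(data=tree_source, **kwargs)
    else:
        tree = dendropy.Tree.get(path=tree_source, **kwargs)
    return [" ".join(t.label.split()) for t in tree.taxon_namespace]


def export_tree_annotation(
    table: pd.DataFrame,
    tree: str,
    out_dir: str | Path,
) -> list[Path]:
    """Write one iTOL DATASET_BINARY-style file per signature column.

    ``tree`` may be a newick string or a path to one. Table ids missing
    from the tree are reported as a warning (never silently matched);
    zero overlap is a hard error. Leaves whose class is ``absent`` are
    omitted from the data section rather than invented.
    """
    leaves = set(_tree_leaf_labels(tree))
    table_ids = [" ".join(str(i).split()) for i in table.index]
    orphans = [i for i in table_ids if i not in leaves]
    if len(orphans) == len(table_ids):
        raise InputError("no overlap between signature table ids and tree leaves")
    if orphans:
        warnings.warn(
            f"{len(orphans)} table id(s) not found in tree: {orphans}",
            stacklevel=2,
        )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    class_cols = [c for c in table.columns if c.startswith("class")]
    written = []
    for col in class_cols:
        pos = col.removeprefix("class")
        path = out_dir / f"signature_{pos}.itol.txt"
        lines = [
            "DATASET_BINARY",
            "SEPARATOR COMMA",
            f"DATASET_LABEL,signature_{pos}",
            "COLOR,#4040c0",
            "FIELD_SHAPES,2",
            f"FIELD_LABELS,pos{pos}",
            "DATA",
        ]
        for raw_id, norm_id in zip(table.index, table_ids):
            if norm_id not in leaves:
                continue
            label = table.at[raw_id, col]
            if label == ABSENT:
                continue
            lines.append(f"{norm_id},{_CODE[label]}")
        path.write_text("\n".join(lines) + "\n")
        written.append(path)
    return written


def parse_tree_annotation(path: str | Path) -> dict[str, str]:
    """Read back an exported annotation file as {leaf id: class label}."""
    out: dict[str, str] = {}
    in_data = False
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not in_data:
            in_data = line == "DATA"
            continue
        if not line:
            continue
        leaf, code = line.rsplit(",", 1)
        out[leaf] = _LABEL[code]
    return out
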