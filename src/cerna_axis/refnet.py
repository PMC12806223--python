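"""Reference ceRNA network assembly from multi-source interaction tables.

A competing-endogenous-RNA (ceRNA) reference network is tripartite:
lncRNA--miRNA edges on one side, miRNA--mRNA edges on the other, with the
miRNA layer shared. Interaction databases (NPInter, ENCORI/starBase,
TargetScan, miRTarBase, miRWalk, miRDB, RNAInter and the like) export such
pairs as flat tables; this module ingests any number of those tables,
harmonizes identifiers, merges them by set union, and tracks per-edge
support (how many distinct databases attest the edge).
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "InteractionRecord",
    "ReferenceNetwork",
    "harmonize_id",
    "load_interaction_table",
    "build_reference",
]

EDGE_CLASSES = ("lnc_mi", "mi_m")

# Species prefixes commonly carried by miRNA names in database exports.
_SPECIES_PREFIX = re.compile(r"^(hsa|mmu|rno)-")


@dataclass(frozen=True)
class InteractionRecord:
    """One regulatory pair: a miRNA and its ceRNA partner (lncRNA or mRNA).

    ``edge_class`` is ``"lnc_mi"`` when the partner is a lncRNA and
    ``"mi_m"`` when it is an mRNA; ``source`` is the free-string database
    label the pair came from.
    """

    partner_a: str
    mirna: str
    edge_class: str
    source: str
    raw_line: str | None = None

    def __post_init__(self) -> None:
        if self.edge_class not in EDGE_CLASSES:
            raise ValueError(
                f"edge_class must be one of {EDGE_CLASSES}, got {self.edge_class!r}"
            )


def harmonize_id(
    raw_id: str,
    kind: str,
    alias_map: Mapping[str, str] | None = None,
) -> str:
    """Normalize an RNA identifier so the same molecule merges across databases.

    Gene symbols are whitespace-stripped and upper-cased. miRNA names are
    lower-cased with the species prefix (``hsa-``/``mmu-``/``rno-``) removed;
    the arm suffix (``-5p``/``-3p``) is preserved. ``alias_map`` (keys in
    normalized form) is applied after normalization.
    """
    if kind not in ("gene", "mirna"):
        raise ValueError(f"kind must be 'gene' or 'mirna', got {kind!r}")
    cleaned = raw_id.strip()
    if not cleaned:
        raise ValueError("empty identifier")
    if kind == "gene":
        out = cleaned.upper()
    else:
        out = _SPECIES_PREFIX.sub("", cleaned.lower())
    if alias_map is not None:
        out = alias_map.get(out, out)
    return out


def load_interaction_table(
    path: str | Path,
    edge_class: str,
    source: str,
    columns: tuple[str, str] | None = None,
    alias_map: Mapping[str, str] | None = None,
    harmonize: bool = True,
) -> list[InteractionRecord]:
    """Parse one interaction TSV into records.

    ``columns`` names the (partner, miRNA) ID columns; when ``None`` the
    first two columns are used. For ``lnc_mi`` tables the partner is the
    lncRNA, for ``mi_m`` the mRNA; either column order ``(partner, mirna)``
    is expected. Blank and malformed rows (missing either ID) are skipped
    and counted in a single warning -- duplicates are kept verbatim, since
    de-duplication is :func:`build_reference`'s job.
    """
    path = Path(path)
    if edge_class not in EDGE_CLASSES:
        raise ValueError(f"edge_class must be one of {EDGE_CLASSES}")
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, skip_blank_lines=False)
    if columns is None:
        if df.shape[1] < 2:
            raise ValueError(f"{path}: need at least two ID columns")
        col_a, col_b = df.columns[:2]
    else:
        col_a, col_b = columns
        for col in (col_a, col_b):
            if col not in df.columns:
                raise ValueError(f"{path}: required ID column {col!r} not found")

    records: list[InteractionRecord] = []
    n_skipped = 0
    for _, row in df.iterrows():
        a, b = row[col_a], row[col_b]
        if pd.isna(a) or pd.isna(b) or not str(a).strip() or not str(b).strip():
            n_skipped += 1
            continue
        a, b = str(a), str(b)
        if harmonize:
            partner = harmonize_id(a, "gene", alias_map)
            mirna = harmonize_id(b, "mirna", alias_map)
        else:
            partner, mirna = a.strip(), b.strip()
        records.append(
            InteractionRecord(
                partner_a=partner,
                mirna=mirna,
                edge_class=edge_class,
                source=source,
                raw_line=f"{a}\t{b}",
            )
        )
    if n_skipped:
        warnings.warn(
            f"{path}: skipped {n_skipped} blank/malformed row(s)", stacklevel=2
        )
    if not records:
        raise ValueError(f"{path}: no parsable interaction rows")
    return records


@dataclass
class ReferenceNetwork:
    """De-duplicated tripartite edge store with per-edge source sets.

    Edges are keyed ``(partner, mirna)``; ``support_count`` of an edge is
    the number of distinct source databases attesting it. ``node_class``
    maps every node to exactly one of ``lncRNA``/``miRNA``/``mRNA``.
    """

    lnc_mi: dict[tuple[str, str], set[str]] = field(default_factory=dict)
    mi_m: dict[tuple[str, str], set[str]] = field(default_factory=dict)
    node_class: dict[str, str] = field(default_factory=dict)

    def support_count(self, edge: tuple[str, str], edge_class: str) -> int:
        store = self.lnc_mi if edge_class == "lnc_mi" else self.mi_m
        return len(store[edge])

    @property
    def n_lnc_mi(self) -> int:
        return len(self.lnc_mi)

    @property
    def n_mi_m(self) -> int:
        return len(self.mi_m)

    def nodes_of_class(self, cls: str) -> set[str]:
        return {n for n, c in self.node_class.items() if c == cls}

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Edge lists as DataFrames (id_a, id_b, support_count, sources)."""

        def _frame(store: dict[tuple[str, str], set[str]]) -> pd.DataFrame:
            rows = [
                {
                    "id_a": a,
                    "id_b": b,
                    "support_count": len(srcs),
                    "sources": ";".join(sorted(srcs)),
                }
                for (a, b), srcs in sorted(store.items())
            ]
            return pd.DataFrame(
                rows, columns=["id_a", "id_b", "support_count", "sources"]
            )

        return _frame(self.lnc_mi), _frame(self.mi_m)

    def write(self, outdir: str | Path) -> dict:
        """Write TSV edge lists plus a JSON summary; return the summary."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        lnc_mi, mi_m = self.to_frames()
        lnc_mi.to_csv(outdir / "reference_lnc_mi.tsv", sep="\t", index=False)
        mi_m.to_csv(outdir / "reference_mi_m.tsv", sep="\t", index=False)
        summary = {
            "n_lnc_mi_edges": self.n_lnc_mi,
            "n_mi_m_edges": self.n_mi_m,
            "n_lncRNA": len(self.nodes_of_class("lncRNA")),
            "n_miRNA": len(self.nodes_of_class("miRNA")),
            "n_mRNA": len(self.nodes_of_class("mRNA")),
        }
        with open(outdir / "reference_summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
        return summary

    @classmethod
    def from_edge_frames(
        cls, lnc_mi: pd.DataFrame, mi_m: pd.DataFrame
    ) -> "ReferenceNetwork":
        """Rebuild a network from its own edge dump (round-trip)."""
        records = []
        for edge_class, df in (("lnc_mi", lnc_mi), ("mi_m", mi_m)):
            for _, row in df.iterrows():
                a, b = str(row["id_a"]), str(row["id_b"])
                partner, mirna = (a, b) if edge_class == "lnc_mi" else (b, a)
                for src in str(row["sources"]).split(";"):
                    records.append(
                        InteractionRecord(
                            partner_a=partner,
                            mirna=mirna,
                            edge_class=edge_class,
                            source=src,
                        )
                    )
        return build_reference(records)


def build_reference(
    records: Iterable[InteractionRecord],
    min_support: int = 1,
) -> ReferenceNetwork:
    """Merge harmonized records into a :class:`ReferenceNetwork`.

    Edges are the set union over sources; support is the count of distinct
    source labels per edge. Node classes follow the edge class (the partner
    of a ``lnc_mi`` edge is a lncRNA, of a ``mi_m`` edge an mRNA). An ID
    appearing as both lncRNA and mRNA (or as miRNA and ceRNA) is a class
    collision and raises. ``min_support`` drops edges attested by fewer
    distinct sources (default keeps everything).
    """
    records = list(records)
    if not records:
        raise ValueError("no interaction records to merge")

    net = ReferenceNetwork()
    claims: dict[str, set[str]] = {}
    for rec in records:
        if rec.partner_a == rec.mirna:
            raise ValueError(f"self-edge after harmonization: {rec.partner_a!r}")
        # lnc_mi edges are keyed (lncRNA, miRNA); mi_m edges (miRNA, mRNA)
        if rec.edge_class == "lnc_mi":
            net.lnc_mi.setdefault((rec.partner_a, rec.mirna), set()).add(rec.source)
        else:
            net.mi_m.setdefault((rec.mirna, rec.partner_a), set()).add(rec.source)
        partner_cls = "lncRNA" if rec.edge_class == "lnc_mi" else "mRNA"
        claims.setdefault(rec.partner_a, set()).add(partner_cls)
        claims.setdefault(rec.mirna, set()).add("miRNA")

    collisions = sorted(n for n, cl in claims.items() if len(cl) > 1)
    if collisions:
        raise ValueError(
            "node class collision (same ID in more than one RNA class): "
            + ", ".join(collisions)
        )
    net.node_class = {n: next(iter(cl)) for n, cl in claims.items()}

    if min_support > 1:
        for store in (net.lnc_mi, net.mi_m):
            for edge in [e for e, s in store.items() if len(s) < min_support]:
                del store[edge]
        kept = {n for e in net.lnc_mi for n in e} | {n for e in net.mi_m for n in e}
        net.node_class = {n: c for n, c in net.node_class.items() if n in kept}
    return net
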