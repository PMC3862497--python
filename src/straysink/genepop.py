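"""Reading and writing genotype collections.

Two plain-text formats: the Genepop dialect (title line, one locus name
per line or a comma-separated line, ``POP``-delimited blocks, individual
lines ``id , 0102 0101 ...`` with fixed-width allele codes where an
all-zero code is missing), and a CSV genotype table (rows = individuals,
columns = loci, values 0/1/2/NA) with a separate metadata CSV carrying
collection, role, site and stray flags.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import MISSING, Collection, CollectionSet

__all__ = ["read_genepop", "write_genepop", "read_csv_genotypes", "write_csv_genotypes"]


def _common_prefix_name(ids: list[str], fallback: str) -> str:
    base = ids[0].rsplit("_", 1)[0]
    if base and all(i.rsplit("_", 1)[0] == base for i in ids):
        return base
    return fallback


def read_genepop(
    path: str | Path,
    roles: dict[str, tuple[str, str]] | None = None,
) -> CollectionSet:
    """Parse a Genepop file into a :class:`CollectionSet`.

    Biallelic loci are mapped to reference-allele counts, the reference
    being the lowest allele code observed at the locus (code 01 for
    panels written by :func:`write_genepop`).  Allele-code width (2 or
    3 digits) is auto-detected from the genotype field length.

    ``roles`` optionally maps collection name -> (role, site); unnamed
    collections default to ``sink-contemporary`` at their own site.
    """
    lines = [l.rstrip("\n") for l in Path(path).read_text().splitlines()]
    if not lines:
        raise ValueError("empty file")
    lines = [l for l in lines if l.strip()]
    # header: title, then locus names until first POP
    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().upper() != "POP":
        if "," in lines[i]:
            loci.extend(x.strip() for x in lines[i].split(",") if x.strip())
        else:
            loci.append(lines[i].strip())
        i += 1
    if i == len(lines):
        raise ValueError("no POP block found")

    blocks: list[list[tuple[str, list[str]]]] = []
    current: list[tuple[str, list[str]]] | None = None
    for line in lines[i:]:
        if line.strip().upper() == "POP":
            if current is not None and not current:
                raise ValueError("empty POP block")
            current = []
            blocks.append(current)
            continue
        if "," not in line:
            raise ValueError(f"malformed individual line: {line!r}")
        ind_id, geno = line.split(",", 1)
        fields = geno.split()
        if len(fields) != len(loci):
            raise ValueError(
                f"individual {ind_id.strip()!r} has {len(fields)} genotypes, "
                f"expected {len(loci)}"
            )
        current.append((ind_id.strip(), fields))
    if current is not None and not current:
        raise ValueError("empty POP block")

    widths = {len(f) for block in blocks for _, row in block for f in row}
    if widths <= {4}:
        width = 2
    elif widths <= {6}:
        width = 3
    else:
        raise ValueError(f"unknown or mixed allele-code width: field lengths {sorted(widths)}")

    # collect allele codes per locus to pick the reference allele
    allele_codes: list[set[int]] = [set() for _ in loci]
    for block in blocks:
        for _, row in block:
            for l, f in enumerate(row):
                a1, a2 = int(f[:width]), int(f[width:])
                for a in (a1, a2):
                    if a != 0:
                        allele_codes[l].add(a)
    for l, codes in enumerate(allele_codes):
        if len(codes) > 2:
            raise ValueError(
                f"locus {loci[l]!r} shows {len(codes)} alleles; only biallelic "
                "SNP panels are read into genotype matrices"
            )
    ref_code = [min(codes) if codes else 1 for codes in allele_codes]

    collections = []
    for bi, block in enumerate(blocks):
        ids = [ind for ind, _ in block]
        geno = np.full((len(block), len(loci)), MISSING, dtype=np.int8)
        for r, (_, row) in enumerate(block):
            for l, f in enumerate(row):
                a1, a2 = int(f[:width]), int(f[width:])
                if a1 == 0 or a2 == 0:
                    continue
                geno[r, l] = (a1 == ref_code[l]) + (a2 == ref_code[l])
        name = _common_prefix_name(ids, f"pop{bi + 1}")
        role, site = (roles or {}).get(name, ("sink-contemporary", name))
        collections.append(Collection(name, geno, ids, role, site))
    return CollectionSet(collections, loci)


def write_genepop(
    collections: CollectionSet, path: str | Path, code_width: int = 2, title: str | None = None
) -> None:
    """Write a CollectionSet as a Genepop file (reference allele coded 01,
    alternate 02, missing all-zero)."""
    if code_width not in (2, 3):
        raise ValueError("code_width must be 2 or 3")
    if not collections.collections:
        raise ValueError("no collections to write")
    if 2 > 10**code_width - 1:
        raise ValueError("allele index exceeds code width")
    codes = {
        2: f"{1:0{code_width}d}{1:0{code_width}d}",
        1: f"{1:0{code_width}d}{2:0{code_width}d}",
        0: f"{2:0{code_width}d}{2:0{code_width}d}",
        MISSING: "0" * (2 * code_width),
    }
    out = [title or "straysink genotype export"]
    out.extend(collections.loci)
    for c in collections:
        out.append("POP")
        for i in range(c.n_individuals):
            row = " ".join(codes[int(g)] for g in c.genotypes[i])
            out.append(f"{c.ids[i]} , {row}")
    Path(path).write_text("\n".join(out) + "\n")


def read_csv_genotypes(path: str | Path, metadata_path: str | Path) -> CollectionSet:
    """Read a CSV genotype table plus a metadata CSV.

    The genotype table has an ``id`` column and one column per locus with
    values 0/1/2 or NA; the metadata maps each id to ``collection``,
    ``role``, ``site`` and an optional boolean ``stray`` column.
    """
    geno = pd.read_csv(path, dtype={"id": str})
    meta = pd.read_csv(metadata_path, dtype={"id": str})
    if "id" not in geno.columns:
        raise ValueError("genotype CSV must have an 'id' column")
    loci = [c for c in geno.columns if c != "id"]
    missing_meta = set(geno["id"]) - set(meta["id"])
    if missing_meta:
        raise ValueError(f"ids missing from metadata: {sorted(missing_meta)[:5]}")
    values = geno[loci].to_numpy(dtype=float)
    bad = ~(np.isnan(values) | np.isin(values, (0.0, 1.0, 2.0)))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"invalid genotype {values[r, c]!r} for id {geno['id'].iloc[r]!r} "
            f"at locus {loci[c]!r}"
        )
    matrix = np.where(np.isnan(values), MISSING, values).astype(np.int8)

    meta = meta.set_index("id")
    collections = []
    for name in meta["collection"].unique():
        ids = [i for i in geno["id"] if meta.loc[i, "collection"] == name]
        rows = [geno.index[geno["id"] == i][0] for i in ids]
        sub_meta = meta.loc[ids]
        role = sub_meta["role"].iloc[0]
        site = sub_meta["site"].iloc[0] if "site" in sub_meta else name
        stray = (
            sub_meta["stray"].astype(bool).to_numpy()
            if "stray" in sub_meta
            else None
        )
        collections.append(Collection(name, matrix[rows], ids, role, site, stray))
    return CollectionSet(collections, loci)


def write_csv_genotypes(
    collections: CollectionSet, path: str | Path, metadata_path: str | Path
) -> None:
    """Inverse of :func:`read_csv_genotypes`."""
    rows, meta_rows = [], []
    for c in collections:
        for i in range(c.n_individuals):
            rows.append(
                [c.ids[i]]
                + [
                    "" if g == MISSING else int(g)
                    for g in c.genotypes[i]
                ]
            )
            meta_rows.append([c.ids[i], c.name, c.role, c.site, bool(c.stray[i])])
    pd.DataFrame(rows, columns=["id"] + list(collections.loci)).to_csv(path, index=False)
    pd.DataFrame(
        meta_rows, columns=["id", "collection", "role", "site", "stray"]
    ).to_csv(metadata_path, index=False)
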