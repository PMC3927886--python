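"""Diploid microsatellite genotype container and GENEPOP text I/O.

The central data structure is :class:`GenotypeMatrix`: individuals grouped
into populations, each carrying an unordered pair of integer allele labels
(repeat sizes) per locus, with fully-missing calls coded as ``(0, 0)``.
Everything downstream — diversity summaries, F-statistics, isolation-by-
distance regression — consumes this container.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "GenepopFormatError",
    "read_genepop",
    "write_genepop",
    "pool_nearby_sites",
]


class GenepopFormatError(ValueError):
    """Raised when a GENEPOP stream violates the 4.x dialect."""


@dataclass
class GenotypeMatrix:
    """Diploid genotypes for individuals grouped into populations.

    Parameters
    ----------
    individual_ids :
        Identifier per individual, in file order.
    populations :
        Population label per individual (parallel to ``individual_ids``).
    loci :
        Ordered locus names.
    calls :
        Integer array of shape ``(n_individuals, n_loci, 2)``; allele labels
        are positive integers and a missing call is ``(0, 0)``.
    """

    individual_ids: list[str]
    populations: list[str]
    loci: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int64)
        if self.calls.shape != (len(self.individual_ids), len(self.loci), 2):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.individual_ids)} individuals x {len(self.loci)} loci"
            )
        if len(self.populations) != len(self.individual_ids):
            raise ValueError("populations must parallel individual_ids")
        half_missing = (self.calls == 0).sum(axis=2) == 1
        if half_missing.any():
            raise ValueError("calls must be fully present or fully missing")
        if (self.calls < 0).any():
            raise ValueError("allele labels must be positive integers")

    # -- structure ---------------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def pop_names(self) -> list[str]:
        """Population labels in order of first appearance."""
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p)
        return list(seen)

    def pop_indices(self, pop: str) -> np.ndarray:
        mask = np.array([p == pop for p in self.populations])
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise KeyError(f"unknown population {pop!r}")
        return idx

    def subset_pops(self, pops: list[str]) -> "GenotypeMatrix":
        idx = np.concatenate([self.pop_indices(p) for p in pops])
        return GenotypeMatrix(
            [self.individual_ids[i] for i in idx],
            [self.populations[i] for i in idx],
            list(self.loci),
            self.calls[idx],
        )

    # -- per-locus views ---------------------------------------------------

    def missing_mask(self) -> np.ndarray:
        """Boolean (n_individuals, n_loci); True where the call is missing."""
        return (self.calls == 0).all(axis=2)

    def missing_rate(self) -> float:
        return float(self.missing_mask().mean())

    def locus_alleles(self, locus: str, pop: str | None = None) -> np.ndarray:
        """Non-missing allele labels at a locus, optionally one population."""
        j = self.loci.index(locus)
        rows = self.pop_indices(pop) if pop is not None else np.arange(self.n_individuals)
        g = self.calls[rows, j, :]
        g = g[(g != 0).all(axis=1)]
        return g.ravel()

    def relabel_populations(self, mapping: dict[str, str]) -> "GenotypeMatrix":
        pops = [mapping.get(p, p) for p in self.populations]
        return GenotypeMatrix(list(self.individual_ids), pops, list(self.loci), self.calls.copy())


# ---------------------------------------------------------------------------
# GENEPOP I/O

_POP_RE = re.compile(r"^pop\s*$", re.IGNORECASE)


def read_genepop(stream, allele_width: int | str = "auto") -> GenotypeMatrix:
    """Parse a GENEPOP 4.x text stream into a :class:`GenotypeMatrix`.

    The title line is ignored; locus names may be one per line or
    comma-separated; populations are delimited by ``POP`` lines (case
    insensitive).  ``0000``/``000000`` (or one all-zero half-width token)
    codes a missing call.

    Parameters
    ----------
    stream :
        A text file object or a string containing the file contents.
    allele_width :
        2 or 3 digits per allele, or ``"auto"`` to infer from token length.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    lines = stream.read().splitlines()
    if len(lines) < 3:
        raise GenepopFormatError("stream too short to be a GENEPOP file")

    # locus names: everything between the title line and the first POP
    loci: list[str] = []
    i = 1
    while i < len(lines) and not _POP_RE.match(lines[i].strip()):
        chunk = lines[i].strip()
        if chunk:
            loci.extend(name.strip() for name in chunk.split(",") if name.strip())
        i += 1
    if i == len(lines):
        raise GenepopFormatError("no POP marker found")
    if not loci:
        raise GenepopFormatError("no locus names before first POP")
    if len(set(loci)) != len(loci):
        dup = sorted({x for x in loci if loci.count(x) > 1})
        raise GenepopFormatError(f"duplicate locus name(s): {', '.join(dup)}")

    individual_ids: list[str] = []
    populations: list[str] = []
    rows: list[list[tuple[int, int]]] = []
    pop_counter = 0
    width = None if allele_width == "auto" else int(allele_width)

    for lineno in range(i, len(lines)):
        raw = lines[lineno]
        line = raw.strip()
        if not line:
            continue
        if _POP_RE.match(line):
            pop_counter += 1
            continue
        if pop_counter == 0:
            raise GenepopFormatError(f"line {lineno + 1}: genotype data before first POP")
        if "," in line:
            ind_id, geno_part = line.split(",", 1)
            ind_id = ind_id.strip()
        else:  # tolerate missing comma: first token is the id
            ind_id, _, geno_part = line.partition(" ")
        tokens = geno_part.split()
        if len(tokens) != len(loci):
            raise GenepopFormatError(
                f"line {lineno + 1}: expected {len(loci)} genotypes, got {len(tokens)}"
            )
        row: list[tuple[int, int]] = []
        for tok in tokens:
            if width is None:
                if len(tok) in (4, 6):
                    width = len(tok) // 2
                else:
                    raise GenepopFormatError(
                        f"line {lineno + 1}: cannot infer allele width from token {tok!r}"
                    )
            if len(tok) != 2 * width or not tok.isdigit():
                raise GenepopFormatError(
                    f"line {lineno + 1}: malformed genotype token {tok!r} "
                    f"(expected {2 * width} digits)"
                )
            a, b = int(tok[:width]), int(tok[width:])
            if (a == 0) != (b == 0):
                # half-missing calls are treated as fully missing
                a = b = 0
            row.append((a, b))
        individual_ids.append(ind_id or f"ind{len(individual_ids) + 1}")
        populations.append(f"pop{pop_counter}")
        rows.append(row)

    if not rows:
        raise GenepopFormatError("no genotype rows after POP markers")
    calls = np.array(rows, dtype=np.int64)
    return GenotypeMatrix(individual_ids, populations, loci, calls)


def write_genepop(gm: GenotypeMatrix, title: str = "coastibd export", width: int = 3) -> str:
    """Serialize to GENEPOP text (line-per-locus header, fixed-width alleles).

    Raises if any allele label does not fit the digit width or if the matrix
    is empty.
    """
    if gm.n_individuals == 0:
        raise ValueError("cannot write a GENEPOP file with no individuals")
    limit = 10**width
    if (gm.calls >= limit).any():
        raise ValueError(f"allele label >= {limit} cannot be encoded at width {width}")
    out = [title]
    out.extend(gm.loci)
    last_pop = None
    for i, (ind, pop) in enumerate(zip(gm.individual_ids, gm.populations)):
        if pop != last_pop:
            out.append("POP")
            last_pop = pop
        toks = [
            f"{a:0{width}d}{b:0{width}d}" for a, b in gm.calls[i]
        ]
        out.append(f"{ind} , " + " ".join(toks))
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# sample pooling

def pool_nearby_sites(
    gm: GenotypeMatrix,
    sites: pd.DataFrame,
    threshold_km: float = 50.0,
    position_col: str = "s_km",
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Pool sampling sites closer than ``threshold_km`` along the coastline.

    Sites are clustered by single linkage on their coastline arc-positions;
    chains of sites each within the threshold of the next therefore merge
    into one population.  The pooled site position is the sample-size
    weighted mean arc-position of its members.

    Returns the pooled genotype matrix (population labels joined with ``+``)
    and the pooled site table.
    """
    from scipy.cluster.hierarchy import fcluster, linkage

    sites = sites.reset_index(drop=True)
    s = sites[position_col].to_numpy(dtype=float)
    if len(s) == 1:
        labels = np.array([1])
    else:
        z = linkage(s[:, None], method="single")
        # fcluster 'distance' keeps clusters whose merge height <= t; use a
        # strict interpretation: links at exactly the threshold still pool.
        labels = fcluster(z, t=threshold_km, criterion="distance")

    pooled_rows = []
    mapping: dict[str, str] = {}
    for lab in sorted(set(labels)):
        members = sites[labels == lab]
        ids = [str(x) for x in members["site_id"]]
        new_id = "+".join(ids)
        n = members["n"].to_numpy(dtype=float)
        w = n / n.sum()
        row = {
            "site_id": new_id,
            "n": int(n.sum()),
            position_col: float((w * members[position_col]).sum()),
        }
        for col in ("lat", "lon"):
            if col in members:
                row[col] = float((w * members[col]).sum())
        if "name" in members:
            row["name"] = "+".join(map(str, members["name"]))
        pooled_rows.append(row)
        for sid in ids:
            mapping[sid] = new_id
    pooled_sites = pd.DataFrame(pooled_rows)
    # genotype population labels may be site ids or popN; map what we can
    pooled_gm = gm.relabel_populations(mapping)
    return pooled_gm, pooled_sites
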