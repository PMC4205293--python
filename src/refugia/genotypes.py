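"""Diploid microsatellite genotype tables.

A :class:`GenotypeDataset` holds allele sizes (integer repeat counts) for a
set of diploid individuals grouped into populations (demes) and typed at a
set of loci.  It is the common currency between the coalescent simulator,
the synthetic-data generators and the summary-statistic estimators.

Alleles are stored as an ``(n_individuals, n_loci, 2)`` integer array with
``-1`` marking a missing gene copy.  Both gene copies of a genotype are
either present or missing together.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1


@dataclass
class GenotypeDataset:
    """Allele-size table for diploid individuals in populations.

    Parameters
    ----------
    alleles
        Integer array of shape ``(n_individuals, n_loci, 2)``; allele sizes
        are repeat counts ``>= 1``, with ``-1`` for missing data.
    pops
        Integer population index per individual (codes into ``pop_names``).
    pop_names, locus_names, individual_ids
        Optional labels; generated when omitted.
    """

    alleles: np.ndarray
    pops: np.ndarray
    pop_names: list[str] = field(default_factory=list)
    locus_names: list[str] = field(default_factory=list)
    individual_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int64)
        self.pops = np.asarray(self.pops, dtype=np.int64)
        if self.alleles.ndim != 3 or self.alleles.shape[2] != 2:
            raise ValueError("alleles must have shape (n_individuals, n_loci, 2)")
        if self.pops.shape != (self.alleles.shape[0],):
            raise ValueError("pops must have one entry per individual")
        n_pops = int(self.pops.max()) + 1 if self.pops.size else 0
        if not self.pop_names:
            self.pop_names = [f"pop{i + 1}" for i in range(n_pops)]
        if not self.locus_names:
            self.locus_names = [f"locus{i + 1}" for i in range(self.alleles.shape[1])]
        if not self.individual_ids:
            self.individual_ids = [f"ind{i + 1}" for i in range(self.alleles.shape[0])]
        valid = (self.alleles >= 1) | (self.alleles == MISSING)
        if not valid.all():
            raise ValueError("allele sizes must be >= 1 (or -1 for missing)")

    # ------------------------------------------------------------------ #
    # basic properties

    @property
    def n_individuals(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_loci(self) -> int:
        return self.alleles.shape[1]

    @property
    def n_populations(self) -> int:
        return len(self.pop_names)

    def population_indices(self, pop: int | str) -> np.ndarray:
        """Row indices of the individuals belonging to one population."""
        code = self.pop_names.index(pop) if isinstance(pop, str) else int(pop)
        return np.flatnonzero(self.pops == code)

    def subset_populations(self, keep: list[int | str]) -> "GenotypeDataset":
        codes = [self.pop_names.index(p) if isinstance(p, str) else int(p) for p in keep]
        mask = np.isin(self.pops, codes)
        remap = {c: i for i, c in enumerate(codes)}
        return GenotypeDataset(
            alleles=self.alleles[mask],
            pops=np.array([remap[c] for c in self.pops[mask]]),
            pop_names=[self.pop_names[c] for c in codes],
            locus_names=list(self.locus_names),
            individual_ids=[self.individual_ids[i] for i in np.flatnonzero(mask)],
        )

    # ------------------------------------------------------------------ #
    # tabular round trips

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table: one row per (individual, locus)."""
        n, L = self.n_individuals, self.n_loci
        return pd.DataFrame(
            {
                "individual_id": np.repeat(self.individual_ids, L),
                "deme_id": np.repeat([self.pop_names[c] for c in self.pops], L),
                "locus_id": np.tile(self.locus_names, n),
                "allele_size_1": self.alleles[:, :, 0].ravel(),
                "allele_size_2": self.alleles[:, :, 1].ravel(),
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "GenotypeDataset":
        required = {"individual_id", "deme_id", "locus_id", "allele_size_1", "allele_size_2"}
        missing_cols = required - set(df.columns)
        if missing_cols:
            raise ValueError(f"missing columns: {sorted(missing_cols)}")
        inds = list(dict.fromkeys(df["individual_id"]))
        loci = list(dict.fromkeys(df["locus_id"].astype(str)))
        pops_per_ind = df.drop_duplicates("individual_id").set_index("individual_id")["deme_id"]
        pop_names = list(dict.fromkeys(pops_per_ind))
        ind_idx = {v: i for i, v in enumerate(inds)}
        loc_idx = {v: i for i, v in enumerate(loci)}
        alleles = np.full((len(inds), len(loci), 2), MISSING, dtype=np.int64)
        rows = df["individual_id"].map(ind_idx).to_numpy()
        cols = df["locus_id"].astype(str).map(loc_idx).to_numpy()
        alleles[rows, cols, 0] = df["allele_size_1"].fillna(MISSING).astype(int)
        alleles[rows, cols, 1] = df["allele_size_2"].fillna(MISSING).astype(int)
        pops = np.array([pop_names.index(pops_per_ind[i]) for i in inds])
        return cls(
            alleles=alleles,
            pops=pops,
            pop_names=[str(p) for p in pop_names],
            locus_names=loci,
            individual_ids=[str(i) for i in inds],
        )

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "GenotypeDataset":
        return cls.from_dataframe(pd.read_csv(path))

    # ------------------------------------------------------------------ #
    # GENEPOP

    def write_genepop(self, path, title: str = "refugia genotype export") -> None:
        """Write the dataset in GENEPOP format with 3-digit allele codes."""
        if (self.alleles[self.alleles != MISSING] > 999).any():
            raise ValueError("allele sizes above 999 cannot be coded in GENEPOP 3-digit form")
        buf = io.StringIO()
        buf.write(title + "\n")
        for name in self.locus_names:
            buf.write(name + "\n")
        for code, pop in enumerate(self.pop_names):
            buf.write("Pop\n")
            for i in self.population_indices(code):
                parts = []
                for l in range(self.n_loci):
                    a, b = self.alleles[i, l]
                    if a == MISSING or b == MISSING:
                        parts.append("000000")
                    else:
                        parts.append(f"{a:03d}{b:03d}")
                buf.write(f"{pop}_{self.individual_ids[i]} , " + " ".join(parts) + "\n")
        with open(path, "w") as fh:
            fh.write(buf.getvalue())

    @classmethod
    def read_genepop(cls, path) -> "GenotypeDataset":
        with open(path) as fh:
            lines = [ln.rstrip("\n") for ln in fh]
        lines = [ln for ln in lines if ln.strip()]
        locus_names: list[str] = []
        i = 1  # skip title
        while i < len(lines) and lines[i].strip().lower() != "pop":
            # loci may be one per line or comma separated
            locus_names.extend(s.strip() for s in lines[i].split(",") if s.strip())
            i += 1
        records: list[tuple[int, str, list[int]]] = []
        pop = -1
        while i < len(lines):
            if lines[i].strip().lower() == "pop":
                pop += 1
                i += 1
                continue
            ind, _, geno = lines[i].partition(",")
            codes = geno.split()
            if len(codes) != len(locus_names):
                raise ValueError(f"line {i + 1}: expected {len(locus_names)} genotypes")
            pairs = []
            for c in codes:
                half = len(c) // 2
                a, b = int(c[:half]), int(c[half:])
                pairs.extend([a if a else MISSING, b if b else MISSING])
            records.append((pop, ind.strip(), pairs))
            i += 1
        alleles = np.array([r[2] for r in records], dtype=np.int64).reshape(len(records), len(locus_names), 2)
        return cls(
            alleles=alleles,
            pops=np.array([r[0] for r in records]),
            locus_names=locus_names,
            individual_ids=[r[1] for r in records],
        )
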