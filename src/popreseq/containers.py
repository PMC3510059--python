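"""In-memory containers shared across the analysis stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

#: canonical cohort table columns, in serialization order
COHORT_COLUMNS = [
    "id",
    "sex",
    "age_at_exam",
    "study",
    "apoa1",
    "hdl",
    "total_chol",
    "triglycerides",
    "ldl",
    "smoking",
    "hypertension",
    "diabetes",
    "entry_age",
    "exit_age",
    "mi_event",
    "prior_mi",
]

LIPID_COLUMNS = ["apoa1", "hdl", "total_chol", "triglycerides", "ldl"]


@dataclass
class Genotypes:
    """Diploid genotypes for a set of variants over one cohort.

    ``matrix`` holds minor-allele dosages (0/1/2), one row per individual in
    cohort order, one column per variant.  ``variants`` is the derived
    per-variant summary (functional class, MAC, MAF, carrier count and
    genotype counts); a carrier is any individual with at least one minor
    allele.
    """

    sample_ids: np.ndarray
    matrix: np.ndarray  # (n_samples, n_variants) int8 dosage
    variants: pd.DataFrame  # indexed by variant_id

    @classmethod
    def from_matrix(
        cls,
        matrix: np.ndarray,
        variant_ids: list[str],
        functional_classes: list[str],
        sample_ids: np.ndarray | list[str],
    ) -> "Genotypes":
        matrix = np.asarray(matrix, dtype=np.int8)
        n, v = matrix.shape
        if len(variant_ids) != v or len(functional_classes) != v:
            raise ValueError("variant annotation length mismatch")
        n_het = (matrix == 1).sum(axis=0)
        n_hom_alt = (matrix == 2).sum(axis=0)
        mac = n_het + 2 * n_hom_alt
        table = pd.DataFrame(
            {
                "functional_class": functional_classes,
                "mac": mac.astype(int),
                "maf": mac / (2.0 * n),
                "carrier_count": (n_het + n_hom_alt).astype(int),
                "n_hom_ref": (n - n_het - n_hom_alt).astype(int),
                "n_het": n_het.astype(int),
                "n_hom_alt": n_hom_alt.astype(int),
            },
            index=pd.Index(variant_ids, name="variant_id"),
        )
        return cls(sample_ids=np.asarray(sample_ids), matrix=matrix, variants=table)

    @property
    def n_individuals(self) -> int:
        return self.matrix.shape[0]

    @property
    def variant_ids(self) -> list[str]:
        return list(self.variants.index)

    def column(self, variant_id: str) -> int:
        try:
            return self.variants.index.get_loc(variant_id)
        except KeyError:
            raise KeyError(f"unknown variant id: {variant_id}") from None

    def dosage(self, variant_id: str) -> np.ndarray:
        return self.matrix[:, self.column(variant_id)]

    def carriers(self, variant_id: str) -> np.ndarray:
        """Row indices of individuals with >= 1 minor allele."""
        return np.nonzero(self.dosage(variant_id) > 0)[0]

    def carrier_map(self) -> dict[str, np.ndarray]:
        return {vid: self.carriers(vid) for vid in self.variant_ids}

    def group_carriers(self, variant_ids: list[str]) -> np.ndarray:
        """Union of carriers over a variant group (each individual once)."""
        cols = [self.column(v) for v in variant_ids]
        if not cols:
            return np.array([], dtype=int)
        return np.nonzero((self.matrix[:, cols] > 0).any(axis=1))[0]

    def drop_monomorphic(self) -> tuple["Genotypes", list[str]]:
        keep = self.variants["mac"].to_numpy() > 0
        dropped = [v for v, k in zip(self.variant_ids, keep) if not k]
        sub = Genotypes(
            sample_ids=self.sample_ids,
            matrix=self.matrix[:, keep],
            variants=self.variants.loc[keep].copy(),
        )
        return sub, dropped


@dataclass
class ResultBundle:
    """Named per-stage result tables plus run metadata.

    Metadata carries everything needed to re-run: seed, config hash and
    package version.  Tables are keyed "<stage>/<name>".
    """

    metadata: dict = field(default_factory=dict)
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)

    def add(self, stage: str, name: str, table: pd.DataFrame) -> None:
        self.tables[f"{stage}/{name}"] = table

    def __iter__(self) -> Iterator[tuple[str, pd.DataFrame]]:
        return iter(self.tables.items())

    def stages(self) -> set[str]:
        return {key.split("/", 1)[0] for key in self.tables}
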