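"""Genotype, phenotype and SNP-manifest I/O.

All downstream modules consume the in-memory containers defined here:
:class:`SnpRecord`, :class:`GenotypeMatrix` and :class:`PhenotypeTable`.
Two on-disk dialects are supported for genotypes: PLINK text (``.ped`` +
``.map``) and a simple TSV matrix (header row of SNP ids, one row per
sample, entries 0/1/2/NA counting effect alleles).

Effect-allele orientation is always taken from the SNP manifest, never
inferred from allele frequency: the effect ("risk") allele of a curated
panel is defined by the source literature per SNP.  PLINK allele pairs are
converted to effect-allele counts on read; an allele not matching the
manifest's effect/other pair raises :class:`OrientationError`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "SnpRecord",
    "GenotypeMatrix",
    "PhenotypeTable",
    "ParseError",
    "OrientationError",
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "write_phenotypes",
    "read_manifest",
    "write_manifest",
    "join_cohort",
]

#: Sentinel for a missing genotype call inside the dosage array (NaN).
MISSING = np.nan

_VALID_ALLELES = frozenset("ACGT")

Dialect = Literal["plink_text", "tsv"]
StatusDialect = Literal["case_control", "zero_one", "plink"]


class ParseError(ValueError):
    """A malformed input line; carries the offending line number."""


class OrientationError(ValueError):
    """An observed allele not in the manifest's {effect, other} pair."""


@dataclass(frozen=True)
class SnpRecord:
    """Identity and allele orientation of one biallelic SNP.

    Parameters
    ----------
    snp_id : str
        rs identifier or arbitrary unique token.
    chrom : str
        Chromosome name (kept as string; "1".."22" typically).
    pos : int
        1-based physical position; non-negative.
    effect_allele : str
        The allele whose count (0/1/2) enters dosages and the PRS.
    other_allele : str
        The non-effect allele; must differ from ``effect_allele``.
    external_weight : float or None
        Optional literature log-OR weight for externally weighted scores.
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    external_weight: float | None = None

    def __post_init__(self) -> None:
        if self.effect_allele not in _VALID_ALLELES:
            raise ValueError(f"{self.snp_id}: invalid effect allele {self.effect_allele!r}")
        if self.other_allele not in _VALID_ALLELES:
            raise ValueError(f"{self.snp_id}: invalid other allele {self.other_allele!r}")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: effect and other allele are both {self.effect_allele!r}")
        if self.pos < 0:
            raise ValueError(f"{self.snp_id}: negative position {self.pos}")


@dataclass
class GenotypeMatrix:
    """Samples x SNPs effect-allele dosage matrix with missingness.

    ``dosage`` is float; non-missing entries are exactly 0.0, 1.0 or 2.0 and
    missing calls are NaN.
    """

    sample_ids: list[str]
    snps: list[SnpRecord]
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        n, m = len(self.sample_ids), len(self.snps)
        if self.dosage.shape != (n, m):
            raise ValueError(
                f"dosage shape {self.dosage.shape} inconsistent with {n} samples x {m} SNPs"
            )
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != m:
            raise ValueError("duplicate SNP ids in manifest")
        ok = np.isnan(self.dosage) | np.isin(self.dosage, (0.0, 1.0, 2.0))
        if not ok.all():
            bad = self.dosage[~ok].flat[0]
            raise ValueError(f"dosage entries must be 0/1/2/NaN, found {bad!r}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    def snp_index(self, snp_id: str) -> int:
        try:
            return self.snp_ids.index(snp_id)
        except ValueError:
            raise KeyError(f"SNP {snp_id!r} not in matrix") from None

    def column(self, snp_id: str) -> np.ndarray:
        return self.dosage[:, self.snp_index(snp_id)]

    def subset(
        self,
        samples: Sequence[str] | None = None,
        snp_ids: Sequence[str] | None = None,
    ) -> "GenotypeMatrix":
        """Return a new matrix restricted to the given samples and/or SNPs
        (order taken from the arguments)."""
        rows = (
            [self.sample_ids.index(s) for s in samples]
            if samples is not None
            else list(range(self.n_samples))
        )
        cols = (
            [self.snp_index(s) for s in snp_ids]
            if snp_ids is not None
            else list(range(self.n_snps))
        )
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in rows],
            snps=[self.snps[j] for j in cols],
            dosage=self.dosage[np.ix_(rows, cols)].copy(),
        )

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.sample_ids == other.sample_ids
            and self.snps == other.snps
            and np.array_equal(self.dosage, other.dosage, equal_nan=True)
        )


@dataclass
class PhenotypeTable:
    """Case/control status and age per sample.

    Backed by a DataFrame with columns ``sample_id`` (unique), ``status``
    (bool, True = case; never missing) and ``age`` (float years, NaN if
    unknown).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "status", "age"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"phenotype table missing columns {sorted(missing)}")
        if self.df["sample_id"].duplicated().any():
            dup = self.df.loc[self.df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValueError(f"duplicate sample id {dup!r}")
        if self.df["status"].isna().any():
            raise ValueError("status may not be missing")
        self.df = self.df.astype({"sample_id": str, "status": bool, "age": float}).reset_index(
            drop=True
        )
        bad_age = self.df["age"].dropna() <= 0
        if bad_age.any():
            raise ValueError("ages must be positive")

    @classmethod
    def from_arrays(
        cls,
        sample_ids: Sequence[str],
        status: Sequence[bool],
        age: Sequence[float] | None = None,
    ) -> "PhenotypeTable":
        n = len(sample_ids)
        return cls(
            pd.DataFrame(
                {
                    "sample_id": list(sample_ids),
                    "status": list(status),
                    "age": list(age) if age is not None else [np.nan] * n,
                }
            )
        )

    @property
    def sample_ids(self) -> list[str]:
        return self.df["sample_id"].tolist()

    @property
    def n_cases(self) -> int:
        return int(self.df["status"].sum())

    @property
    def n_controls(self) -> int:
        return int((~self.df["status"]).sum())

    def aligned_to(self, sample_ids: Sequence[str]) -> "PhenotypeTable":
        """Return a table reindexed to ``sample_ids`` order (all must exist)."""
        indexed = self.df.set_index("sample_id")
        missing = [s for s in sample_ids if s not in indexed.index]
        if missing:
            raise KeyError(f"samples absent from phenotype table: {missing[:5]}")
        out = indexed.loc[list(sample_ids)].reset_index()
        return PhenotypeTable(out)

    def status_array(self, sample_ids: Sequence[str] | None = None) -> np.ndarray:
        t = self if sample_ids is None else self.aligned_to(sample_ids)
        return t.df["status"].to_numpy(dtype=bool)

    def age_array(self, sample_ids: Sequence[str] | None = None) -> np.ndarray:
        t = self if sample_ids is None else self.aligned_to(sample_ids)
        return t.df["age"].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# manifest


def read_manifest(path: str | Path) -> list[SnpRecord]:
    """Read a SNP manifest TSV.

    Columns: snp_id, chrom, pos, effect_allele, other_allele and optionally
    external_weight (log-OR scale; blank/NA allowed).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"snp_id", "chrom", "pos", "effect_allele", "other_allele"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"manifest {path}: missing columns {sorted(missing)}")
    records = []
    for i, row in df.iterrows():
        w = None
        if "external_weight" in df.columns:
            raw = row["external_weight"]
            if isinstance(raw, str) and raw.strip() not in ("", "NA", "nan"):
                w = float(raw)
        records.append(
            SnpRecord(
                snp_id=row["snp_id"],
                chrom=str(row["chrom"]),
                pos=int(row["pos"]),
                effect_allele=row["effect_allele"].strip().upper(),
                other_allele=row["other_allele"].strip().upper(),
                external_weight=w,
            )
        )
    ids = [r.snp_id for r in records]
    if len(set(ids)) != len(ids):
        raise ParseError(f"manifest {path}: duplicate snp ids")
    return records


def write_manifest(snps: Iterable[SnpRecord], path: str | Path) -> None:
    rows = [dataclasses.asdict(s) for s in snps]
    df = pd.DataFrame(rows)
    df["external_weight"] = df["external_weight"].map(
        lambda w: "NA" if w is None else repr(float(w))
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genotypes


def read_genotypes(
    path: str | Path,
    dialect: Dialect,
    manifest: Sequence[SnpRecord] | None = None,
) -> GenotypeMatrix:
    """Read a genotype matrix oriented to the manifest's effect alleles.

    Parameters
    ----------
    path : str or Path
        For ``plink_text`` the shared prefix of ``<prefix>.ped`` and
        ``<prefix>.map``; for ``tsv`` the file path.
    dialect : {"plink_text", "tsv"}
    manifest : sequence of SnpRecord
        Required: supplies allele orientation (plink_text) and SNP metadata
        (tsv).  Manifest order must cover every SNP in the file.
    """
    if manifest is None:
        raise ValueError("a SNP manifest is required to orient effect alleles")
    if dialect == "plink_text":
        return _read_plink_text(Path(path), list(manifest))
    if dialect == "tsv":
        return _read_tsv(Path(path), list(manifest))
    raise ValueError(f"unknown dialect {dialect!r}")


def write_genotypes(gm: GenotypeMatrix, path: str | Path, dialect: Dialect) -> None:
    """Write ``gm`` in the chosen dialect, losslessly for dosage + missing."""
    if dialect == "plink_text":
        _write_plink_text(gm, Path(path))
    elif dialect == "tsv":
        _write_tsv(gm, Path(path))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def _read_tsv(path: Path, manifest: list[SnpRecord]) -> GenotypeMatrix:
    by_id = {s.snp_id: s for s in manifest}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if not header or header[0] != "sample_id":
            raise ParseError(f"{path}:1: first header column must be 'sample_id'")
        snp_ids = header[1:]
        unknown = [s for s in snp_ids if s not in by_id]
        if unknown:
            raise ParseError(f"{path}:1: SNPs absent from manifest: {unknown[:5]}")
        sample_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(header)} fields, found {len(parts)}"
                )
            sample_ids.append(parts[0])
            row = []
            for tok, sid in zip(parts[1:], snp_ids):
                tok = tok.strip()
                if tok in ("NA", "", "nan"):
                    row.append(np.nan)
                elif tok in ("0", "1", "2"):
                    row.append(float(tok))
                else:
                    raise ParseError(f"{path}:{lineno}: bad dosage {tok!r} at SNP {sid}")
            rows.append(row)
    dosage = np.array(rows, dtype=float) if rows else np.empty((0, len(snp_ids)))
    return GenotypeMatrix(sample_ids, [by_id[s] for s in snp_ids], dosage)


def _write_tsv(gm: GenotypeMatrix, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(["sample_id", *gm.snp_ids]) + "\n")
        for i, sid in enumerate(gm.sample_ids):
            toks = [
                "NA" if np.isnan(v) else str(int(v)) for v in gm.dosage[i]
            ]
            fh.write("\t".join([sid, *toks]) + "\n")


def _read_plink_text(prefix: Path, manifest: list[SnpRecord]) -> GenotypeMatrix:
    map_path = prefix.with_suffix(".map")
    ped_path = prefix.with_suffix(".ped")
    by_id = {s.snp_id: s for s in manifest}
    snps: list[SnpRecord] = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if len(parts) < 4:
                raise ParseError(f"{map_path}:{lineno}: expected 4 columns")
            snp_id = parts[1]
            if snp_id not in by_id:
                raise ParseError(f"{map_path}:{lineno}: SNP {snp_id!r} absent from manifest")
            snps.append(by_id[snp_id])
    m = len(snps)
    sample_ids: list[str] = []
    rows: list[list[float]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if len(parts) != 6 + 2 * m:
                raise ParseError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * m} fields, found {len(parts)}"
                )
            sample_ids.append(parts[1])  # IID
            row = []
            for j, snp in enumerate(snps):
                a1, a2 = parts[6 + 2 * j], parts[7 + 2 * j]
                if a1 == "0" and a2 == "0":
                    row.append(np.nan)
                    continue
                dose = 0.0
                for a in (a1, a2):
                    if a == snp.effect_allele:
                        dose += 1.0
                    elif a != snp.other_allele:
                        raise OrientationError(
                            f"{ped_path}:{lineno}: allele {a!r} at SNP {snp.snp_id} "
                            f"not in {{{snp.effect_allele},{snp.other_allele}}}"
                        )
                row.append(dose)
            rows.append(row)
    dosage = np.array(rows, dtype=float) if rows else np.empty((0, m))
    return GenotypeMatrix(sample_ids, snps, dosage)


def _write_plink_text(gm: GenotypeMatrix, prefix: Path) -> None:
    with open(prefix.with_suffix(".map"), "w") as fh:
        for s in gm.snps:
            fh.write(f"{s.chrom}\t{s.snp_id}\t0\t{s.pos}\n")
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, sid in enumerate(gm.sample_ids):
            fields = [sid, sid, "0", "0", "0", "0"]
            for j, s in enumerate(gm.snps):
                v = gm.dosage[i, j]
                if np.isnan(v):
                    fields += ["0", "0"]
                elif v == 2:
                    fields += [s.effect_allele, s.effect_allele]
                elif v == 1:
                    fields += [s.effect_allele, s.other_allele]
                else:
                    fields += [s.other_allele, s.other_allele]
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# phenotypes


def read_phenotypes(
    path: str | Path, status_dialect: StatusDialect = "case_control"
) -> PhenotypeTable:
    """Read a phenotype TSV with columns sample_id, status, age.

    Status parsing is case-insensitive and governed by ``status_dialect``:
    ``case_control`` ("case"/"control"), ``zero_one`` (1=case, 0=control),
    ``plink`` (2=case, 1=control).  Missing age is "NA" or blank.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "status", "age"}
    if missing := required - set(df.columns):
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    mapping = {
        "case_control": {"case": True, "control": False},
        "zero_one": {"1": True, "0": False},
        "plink": {"2": True, "1": False},
    }[status_dialect]
    status = []
    for i, raw in enumerate(df["status"], start=2):
        key = str(raw).strip().lower()
        if key not in mapping:
            raise ParseError(f"{path}:{i}: unparseable status {raw!r} for dialect {status_dialect}")
        status.append(mapping[key])
    age = [
        np.nan if (not isinstance(a, str)) or a.strip() in ("", "NA", "nan") else float(a)
        for a in df["age"]
    ]
    return PhenotypeTable.from_arrays(df["sample_id"].tolist(), status, age)


def write_phenotypes(
    phen: PhenotypeTable, path: str | Path, status_dialect: StatusDialect = "case_control"
) -> None:
    rev = {
        "case_control": ("case", "control"),
        "zero_one": ("1", "0"),
        "plink": ("2", "1"),
    }[status_dialect]
    out = phen.df.copy()
    out["status"] = np.where(out["status"], rev[0], rev[1])
    out["age"] = out["age"].map(lambda a: "NA" if np.isnan(a) else repr(float(a)))
    out.to_csv(path, sep="\t", index=False)


@dataclass
class JoinReport:
    """Reconciliation of a genotype/phenotype join by sample id."""

    n_joined: int
    genotype_only: list[str] = field(default_factory=list)
    phenotype_only: list[str] = field(default_factory=list)


def join_cohort(
    gm: GenotypeMatrix, phen: PhenotypeTable
) -> tuple[GenotypeMatrix, PhenotypeTable, JoinReport]:
    """Intersect a genotype matrix and phenotype table by sample id.

    Sample order follows the genotype matrix; samples present on one side
    only are excluded and reported, never silently dropped.
    """
    phen_ids = set(phen.sample_ids)
    geno_ids = set(gm.sample_ids)
    keep = [s for s in gm.sample_ids if s in phen_ids]
    report = JoinReport(
        n_joined=len(keep),
        genotype_only=sorted(geno_ids - phen_ids),
        phenotype_only=sorted(phen_ids - geno_ids),
    )
    return gm.subset(samples=keep), phen.aligned_to(keep), report
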