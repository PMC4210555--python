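"""File formats: HapMap and numeric genotype text, phenotype/covariate
tables, kinship CSV and association-result TSV.

All other modules are format-agnostic and consume the in-memory
containers; alignment of individuals across the three inputs happens
here, once, before any modelling.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import CovariateTable, GenotypeMatrix, PhenotypeVector

__all__ = [
    "ParseError",
    "read_genotypes",
    "read_phenotype",
    "read_covariates",
    "align_individuals",
    "write_association",
    "read_association",
    "write_genotypes_numeric",
]

# HapMap text: 11 metadata columns, then one column per individual
_HAPMAP_META = 11
_MISSING_CODES = {"NA", "NN", "N", "", "-", "NaN", "nan", "--"}


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


def read_genotypes(path, format: str = "numeric") -> GenotypeMatrix:
    """Read a genotype file into minor-allele dosage coding.

    ``numeric``: header row of individual ids, then rows of
    marker_id, chrom, pos followed by 0/1/2/NA codes (tab or comma
    separated).  ``hapmap``: standard HapMap text with diploid calls as
    IUPAC allele pairs ("AA", "AG", ..., "NN" missing).  Heterozygotes
    code to 1; homozygotes are oriented so the minor allele is counted
    (frequency <= 0.5).  Monomorphic markers are retained but flagged.
    """
    if format == "numeric":
        return _read_numeric(path)
    if format == "hapmap":
        return _read_hapmap(path)
    raise ValueError(f"unknown genotype format {format!r}; valid: numeric, hapmap")


def _split(line: str) -> list[str]:
    sep = "\t" if "\t" in line else ","
    return [f.strip() for f in line.rstrip("\n").split(sep)]


def _read_numeric(path) -> GenotypeMatrix:
    with open(path) as fh:
        lines = [ln for ln in fh if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = _split(lines[0])
    ids = header[3:]
    if not ids:
        raise ParseError(f"{path}: line 1: no individual columns")
    rows, meta = [], []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = _split(line)
        if len(fields) != 3 + len(ids):
            raise ParseError(
                f"{path}: line {lineno}: expected {3 + len(ids)} fields, got {len(fields)}"
            )
        mid, chrom, pos = fields[:3]
        try:
            pos_i = int(pos)
            if pos_i < 0:
                raise ValueError
        except ValueError:
            raise ParseError(f"{path}: line {lineno}: bad position {pos!r}") from None
        vals = []
        for f in fields[3:]:
            if f in _MISSING_CODES:
                vals.append(np.nan)
                continue
            try:
                v = float(f)
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}: bad genotype code {f!r}"
                ) from None
            if v not in (0.0, 1.0, 2.0):
                raise ParseError(f"{path}: line {lineno}: bad genotype code {f!r}")
            vals.append(v)
        rows.append(vals)
        meta.append((mid, _maybe_int(chrom), pos_i))
    values = np.array(rows, dtype=float).T  # individuals x markers
    values = _orient_minor(values)
    markers = pd.DataFrame(meta, columns=["id", "chrom", "pos"])
    return GenotypeMatrix(values, ids, markers)


def _read_hapmap(path) -> GenotypeMatrix:
    with open(path) as fh:
        lines = [ln for ln in fh if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = _split(lines[0])
    if len(header) <= _HAPMAP_META:
        raise ParseError(f"{path}: line 1: no individual columns after metadata")
    ids = header[_HAPMAP_META:]
    rows, meta = [], []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = _split(line)
        if len(fields) != len(header):
            raise ParseError(
                f"{path}: line {lineno}: expected {len(header)} fields, got {len(fields)}"
            )
        mid, alleles, chrom, pos = fields[0], fields[1], fields[2], fields[3]
        try:
            pos_i = int(pos)
        except ValueError:
            raise ParseError(f"{path}: line {lineno}: bad position {pos!r}") from None
        calls = fields[_HAPMAP_META:]
        allele_set = [a for a in alleles.replace("/", "") if a.isalpha()]
        counts: dict[str, int] = {}
        parsed = []
        for call in calls:
            if call in _MISSING_CODES:
                parsed.append(None)
                continue
            if len(call) != 2 or not call.isalpha():
                raise ParseError(f"{path}: line {lineno}: bad call {call!r}")
            parsed.append(call)
            for a in call:
                counts[a] = counts.get(a, 0) + 1
        observed = sorted(counts)
        if len(observed) > 2:
            raise ParseError(
                f"{path}: line {lineno}: more than two alleles observed"
            )
        ref = None  # allele counted by the dosage; fixed below to the minor one
        pool = observed or allele_set[:1]
        if len(pool) == 1:
            ref = pool[0]
        else:
            a, b = pool[0], pool[1]
            ref = a if counts.get(a, 0) <= counts.get(b, 0) else b
        vals = []
        for call in parsed:
            if call is None:
                vals.append(np.nan)
            else:
                vals.append(float(sum(1 for a in call if a == ref)))
        rows.append(vals)
        meta.append((mid, _maybe_int(chrom), pos_i))
    values = np.array(rows, dtype=float).T
    values = _orient_minor(values)
    markers = pd.DataFrame(meta, columns=["id", "chrom", "pos"])
    return GenotypeMatrix(values, ids, markers)


def _orient_minor(values: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(values, axis=0) / 2.0
    flip = freq > 0.5
    values[:, flip] = 2.0 - values[:, flip]
    return values


def _maybe_int(chrom: str):
    try:
        return int(chrom)
    except ValueError:
        return chrom


def write_genotypes_numeric(g: GenotypeMatrix, path) -> None:
    """Numeric genotype TSV, the inverse of read_genotypes(format='numeric')."""
    with open(path, "w") as fh:
        fh.write("marker\tchrom\tpos\t" + "\t".join(map(str, g.individual_ids)) + "\n")
        for j in range(g.n_markers):
            rec = g.markers.iloc[j]
            codes = [
                "NA" if not np.isfinite(v) else str(int(v)) for v in g.values[:, j]
            ]
            fh.write(f"{rec['id']}\t{rec['chrom']}\t{rec['pos']}\t" + "\t".join(codes) + "\n")


def read_phenotype(path, trait: str | None = None) -> PhenotypeVector:
    """Phenotype TSV/CSV: id column then one column per trait."""
    df = pd.read_csv(path, sep=None, engine="python")
    if df.shape[1] < 2:
        raise ParseError(f"{path}: need an id column and at least one trait column")
    name = trait if trait is not None else df.columns[1]
    if name not in df.columns:
        raise ParseError(f"{path}: trait {name!r} not found")
    return PhenotypeVector(
        df[name].to_numpy(dtype=float), name, [str(i) for i in df.iloc[:, 0]]
    )


def read_covariates(path) -> CovariateTable:
    """Covariate TSV/CSV: id column then one column per covariate."""
    df = pd.read_csv(path, sep=None, engine="python")
    if df.shape[1] < 2:
        raise ParseError(f"{path}: need an id column and at least one covariate")
    return CovariateTable(
        df.iloc[:, 1:].to_numpy(dtype=float),
        list(df.columns[1:]),
        [str(i) for i in df.iloc[:, 0]],
    )


def align_individuals(
    g: GenotypeMatrix,
    y: PhenotypeVector,
    X: CovariateTable | None = None,
) -> tuple[GenotypeMatrix, PhenotypeVector, CovariateTable]:
    """Restrict all inputs to the sorted intersection of individual ids.

    Individuals with a missing phenotype are dropped; the operation is
    idempotent.  Raises on an empty intersection.
    """
    ids = set(g.individual_ids) & set(y.individual_ids or g.individual_ids)
    if X is not None and X.individual_ids:
        ids &= set(X.individual_ids)
    y_ids = y.individual_ids or list(g.individual_ids)
    missing = {i for i, v in zip(y_ids, y.y) if not np.isfinite(v)}
    ids -= missing
    if not ids:
        raise ValueError("no individuals shared across genotype/phenotype/covariates")
    order = sorted(ids)
    g_idx = {v: i for i, v in enumerate(g.individual_ids)}
    y_idx = {v: i for i, v in enumerate(y_ids)}
    g2 = g.subset(np.array([g_idx[i] for i in order]))
    y2 = y.subset(np.array([y_idx[i] for i in order]))
    if y2.individual_ids == []:
        y2.individual_ids = order
    if X is None:
        X2 = CovariateTable.empty(len(order), order)
    else:
        x_ids = X.individual_ids or list(g.individual_ids)
        x_idx = {v: i for i, v in enumerate(x_ids)}
        X2 = X.subset(np.array([x_idx[i] for i in order]))
        X2.validate()
    return g2, y2, X2


_ASSOC_COLUMNS = ["marker", "chrom", "pos", "maf", "effect", "F", "df1", "df2", "p_value"]


def write_association(results: pd.DataFrame, path) -> None:
    """Association TSV sorted by (chrom, pos); round-trips bit-exactly.

    Floating-point columns are serialized with 17 significant digits
    (repr-exact for doubles).
    """
    if results is None or len(results) == 0:
        raise ValueError("association results are empty")
    cols = [c for c in results.columns if c in _ASSOC_COLUMNS + ["q_value", "testable"]]
    out = results[cols].sort_values(["chrom", "pos"], kind="stable")
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_association(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
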