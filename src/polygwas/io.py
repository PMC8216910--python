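"""Reading genotype, phenotype, map and configuration files.

The canonical in-memory genotype representation is the ALT-allele dosage:
an integer in ``0..ploidy`` per marker and sample (``NaN`` = missing),
together with a marker map (id, chromosome, position, ref, alt).  Letter
genotypes such as ``AAAT`` are a presentation form derived from the dosage.

Five genotype dialects are supported:

``gwaspoly``
    Wide table ``Marker, Chrom, Position[, Ref, Alt], <sample>...`` with
    ACGT string calls (e.g. ``AAAT``).  Self-contained.
``vcf``
    VCF 4.x with ploidy-many alleles in ``GT`` (e.g. ``0/0/0/1``).
    Self-contained; biallelic SNPs only.
``matrix``
    Wide numeric dosage table ``Marker, <sample>...``; needs a map file.
``fitpoly``
    Long table ``MarkerName, SampleName, geno`` (posterior-mode dosage);
    needs a map file.
``updog``
    Long table ``snp, ind, geno`` (posterior-mode dosage); needs a map file.

The separate map file has columns ``Marker, Chrom, Position, Ref, Alt``.
All coordinates are 1-based inclusive.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigError, FormatError

logger = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")

#: genotype cell values normalized to the missing sentinel (NaN)
MISSING_CODES = {"NA", "NAN", ".", "", "-", "./.", "./././."}

GENOTYPE_FORMATS = ("gwaspoly", "vcf", "matrix", "fitpoly", "updog")
ENGINE_NAMES = ("poly_full", "poly_naive", "dip_a", "dip_b")

MAP_COLUMNS = ["marker", "chrom", "pos", "ref", "alt"]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

def validate_marker_map(markers: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize a marker map data frame.

    Expects columns ``marker, chrom, pos, ref, alt`` (any order, extra
    columns preserved).  Returns a copy with canonical dtypes.
    """
    missing = [c for c in MAP_COLUMNS if c not in markers.columns]
    if missing:
        raise FormatError(f"marker map lacks columns: {missing}")
    m = markers.copy().reset_index(drop=True)
    m["marker"] = m["marker"].astype(str)
    m["chrom"] = m["chrom"].astype(str)
    m["pos"] = pd.to_numeric(m["pos"], errors="raise").astype(int)
    for col in ("ref", "alt"):
        m[col] = m[col].astype(str).str.upper()
        bad = ~m[col].isin(BASES)
        if bad.any():
            raise FormatError(
                f"non-ACGT {col} allele for markers {m.loc[bad, 'marker'].tolist()[:5]}"
            )
    if m["marker"].duplicated().any():
        dupes = m.loc[m["marker"].duplicated(), "marker"].tolist()[:5]
        raise FormatError(f"duplicate marker ids: {dupes}")
    if (m["pos"] < 1).any():
        raise FormatError("marker positions must be >= 1 (1-based)")
    if (m["ref"] == m["alt"]).any():
        bad_ids = m.loc[m["ref"] == m["alt"], "marker"].tolist()[:5]
        raise FormatError(f"ref == alt for markers {bad_ids}")
    if (m["chrom"].str.len() == 0).any():
        raise FormatError("empty chromosome name")
    return m


@dataclass
class GenotypeMatrix:
    """Markers x samples dosage matrix plus marker map.

    Attributes
    ----------
    ploidy : int
        2 (diploid) or 4 (autotetraploid).
    markers : pandas.DataFrame
        One row per marker: ``marker, chrom, pos, ref, alt``.
    samples : list of str
        Sample identifiers, column order of ``dosage``.
    dosage : numpy.ndarray, shape (n_markers, n_samples)
        ALT-allele dosage in ``0..ploidy``; ``NaN`` encodes missing.
    """

    ploidy: int
    markers: pd.DataFrame
    samples: list[str]
    dosage: np.ndarray

    def __post_init__(self) -> None:
        if self.ploidy not in (2, 4):
            raise FormatError(f"unsupported ploidy {self.ploidy}; only 2 and 4")
        self.markers = validate_marker_map(self.markers)
        self.samples = [str(s) for s in self.samples]
        if len(set(self.samples)) != len(self.samples):
            raise FormatError("duplicate sample ids in genotype")
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.markers), len(self.samples)):
            raise FormatError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.markers)} markers x {len(self.samples)} samples"
            )
        with np.errstate(invalid="ignore"):
            bad = (self.dosage < 0) | (self.dosage > self.ploidy)
        if np.any(bad):
            i, j = np.argwhere(bad)[0]
            raise FormatError(
                f"dosage {self.dosage[i, j]} outside 0..{self.ploidy} at marker "
                f"{self.markers['marker'].iloc[i]}, sample {self.samples[j]}"
            )

    # -- convenience views ---------------------------------------------------

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def marker_ids(self) -> pd.Index:
        return pd.Index(self.markers["marker"])

    def acgt_call(self, i: int, j: int) -> str:
        """Letter genotype for marker row i, sample column j ('NA' if missing)."""
        d = self.dosage[i, j]
        if np.isnan(d):
            return "NA"
        ref = self.markers["ref"].iloc[i]
        alt = self.markers["alt"].iloc[i]
        d = int(d)
        return ref * (self.ploidy - d) + alt * d

    def to_acgt_frame(self) -> pd.DataFrame:
        """Letter-genotype table (markers x samples), missing as 'NA'."""
        data = {
            s: [self.acgt_call(i, j) for i in range(self.n_markers)]
            for j, s in enumerate(self.samples)
        }
        return pd.DataFrame(data, index=self.marker_ids)

    def subset_markers(self, keep: Sequence[bool] | np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep, dtype=bool)
        return GenotypeMatrix(
            ploidy=self.ploidy,
            markers=self.markers.loc[keep].reset_index(drop=True),
            samples=list(self.samples),
            dosage=self.dosage[keep, :],
        )

    def subset_samples(self, sample_ids: Iterable[str]) -> "GenotypeMatrix":
        wanted = list(sample_ids)
        idx = {s: j for j, s in enumerate(self.samples)}
        cols = [idx[s] for s in wanted]
        return GenotypeMatrix(
            ploidy=self.ploidy,
            markers=self.markers.copy(),
            samples=wanted,
            dosage=self.dosage[:, cols],
        )


@dataclass
class PhenotypeTable:
    """Quantitative trait values per sample (NaN = missing)."""

    samples: list[str]
    traits: pd.DataFrame  # index = samples, one numeric column per trait

    def __post_init__(self) -> None:
        self.samples = [str(s) for s in self.samples]
        if len(set(self.samples)) != len(self.samples):
            raise FormatError("duplicate sample ids in phenotype")
        if self.traits.shape[1] < 1:
            raise FormatError("phenotype table has no trait columns")
        self.traits = self.traits.astype(float)
        self.traits.index = pd.Index(self.samples)

    @property
    def trait_names(self) -> list[str]:
        return list(self.traits.columns)

    def trait_vector(self, name: str, sample_order: Sequence[str]) -> np.ndarray:
        return self.traits[name].reindex(list(sample_order)).to_numpy(dtype=float)

    def subset_samples(self, sample_ids: Iterable[str]) -> "PhenotypeTable":
        wanted = [str(s) for s in sample_ids]
        return PhenotypeTable(samples=wanted, traits=self.traits.loc[wanted].copy())


@dataclass
class FilterSettings:
    """Quality-control thresholds; ``None`` disables a filter."""

    maf: float | None = 0.01
    mind: float | None = 0.1
    geno: float | None = 0.1
    hwe: float | None = None

    def __post_init__(self) -> None:
        for name in ("maf", "mind", "geno", "hwe"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ConfigError(f"filter threshold {name}={v} outside [0, 1]")


@dataclass
class RunConfig:
    """Parsed run configuration (one ``KEY: value`` pair per line on disk)."""

    genotype_path: str
    phenotype_path: str
    ploidy: int = 4
    genotype_format: str = "gwaspoly"
    map_path: str | None = None
    gwas_model: str = "full"
    test_model: str = "additive"
    significance: float = 0.05
    correction: str = "bonferroni"
    n_best: int = 10
    filters: FilterSettings = field(default_factory=FilterSettings)
    engines: tuple[str, ...] = ENGINE_NAMES
    ld_r2: float = 0.9
    n_chromosomes: int | None = None
    name: str = "run"

    def __post_init__(self) -> None:
        if self.genotype_format not in GENOTYPE_FORMATS:
            raise ConfigError(
                f"unknown genotype format '{self.genotype_format}'; "
                f"expected one of {GENOTYPE_FORMATS}"
            )
        if self.ploidy not in (2, 4):
            raise ConfigError(f"PLOIDY must be 2 or 4, got {self.ploidy}")
        if self.gwas_model not in ("naive", "full"):
            raise ConfigError(f"GWAS_MODEL must be naive or full, got '{self.gwas_model}'")
        if self.test_model not in ("additive", "dominant", "all"):
            raise ConfigError(
                f"TEST_MODEL must be additive, dominant or all, got '{self.test_model}'"
            )
        if not (0.0 < self.significance < 1.0):
            raise ConfigError(f"SIGNIFICANCE must lie in (0,1), got {self.significance}")
        if self.correction not in ("bonferroni", "fdr"):
            raise ConfigError(f"CORRECTION must be bonferroni or fdr, got '{self.correction}'")
        if self.n_best < 1:
            raise ConfigError(f"N_BEST must be >= 1, got {self.n_best}")
        if not (0.0 <= self.ld_r2 <= 1.0):
            raise ConfigError(f"LD_R2 must lie in [0,1], got {self.ld_r2}")
        bad = [e for e in self.engines if e not in ENGINE_NAMES]
        if bad:
            raise ConfigError(f"unknown engines {bad}; expected subset of {ENGINE_NAMES}")
        if not self.engines:
            raise ConfigError("no engines selected")
        if self.genotype_format in ("matrix", "fitpoly", "updog") and not self.map_path:
            raise ConfigError(f"format '{self.genotype_format}' requires MAP_FILE")


# ---------------------------------------------------------------------------
# configuration parsing
# ---------------------------------------------------------------------------

_CONFIG_KEYS = {
    "GENOTYPE_FILE", "PHENOTYPE_FILE", "MAP_FILE", "PLOIDY", "FORMAT",
    "GWAS_MODEL", "TEST_MODEL", "SIGNIFICANCE", "CORRECTION", "N_BEST",
    "MAF", "MIND", "GENO", "HWE", "TOOLS", "LD_R2", "N_CHROMS",
}


def _parse_filter_value(key: str, raw: str, default: float) -> float | None:
    """TRUE -> default threshold, FALSE/NULL -> disabled, number -> threshold."""
    token = raw.strip().upper()
    if token in ("NULL", "FALSE", "NONE", ""):
        return None
    if token == "TRUE":
        return default
    try:
        return float(token)
    except ValueError:
        raise ConfigError(f"non-numeric threshold for {key}: '{raw}'") from None


def read_config(path: str | Path) -> RunConfig:
    """Parse a colon-separated ``KEY: value`` configuration file.

    Omitted keys take documented defaults (significance 0.05, Bonferroni
    correction, all four engines on).  ``NULL`` means "no value"; filter
    switches accept ``TRUE``/``FALSE``.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"configuration file not found: {path}")
    raw: dict[str, str] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if ":" not in line:
            raise ConfigError(f"{path}:{lineno}: expected 'KEY: value', got '{line}'")
        key, _, value = line.partition(":")
        key = key.strip().upper()
        if key not in _CONFIG_KEYS:
            logger.warning("%s:%d: ignoring unknown configuration key '%s'", path, lineno, key)
            continue
        raw[key] = value.strip()

    def get(key: str, default: str | None = None) -> str | None:
        v = raw.get(key, default)
        if v is not None and v.upper() == "NULL":
            return None
        return v

    geno_file = get("GENOTYPE_FILE")
    pheno_file = get("PHENOTYPE_FILE")
    if not geno_file:
        raise ConfigError("missing mandatory key GENOTYPE_FILE")
    if not pheno_file:
        raise ConfigError("missing mandatory key PHENOTYPE_FILE")

    def get_num(key: str, default: float, caster=float):
        v = get(key)
        if v is None:
            return default
        try:
            return caster(v)
        except ValueError:
            raise ConfigError(f"non-numeric value for {key}: '{v}'") from None

    tools = get("TOOLS")
    engines = (
        tuple(t.strip() for t in tools.replace(",", " ").split() if t.strip())
        if tools
        else ENGINE_NAMES
    )
    n_chroms_raw = get("N_CHROMS")
    filters = FilterSettings(
        maf=_parse_filter_value("MAF", raw.get("MAF", "TRUE"), 0.01),
        mind=_parse_filter_value("MIND", raw.get("MIND", "TRUE"), 0.1),
        geno=_parse_filter_value("GENO", raw.get("GENO", "TRUE"), 0.1),
        hwe=_parse_filter_value("HWE", raw.get("HWE", "NULL"), 0.05),
    )
    base = path.parent

    def resolve(p: str | None) -> str | None:
        if p is None:
            return None
        q = Path(p)
        return str(q if q.is_absolute() else base / q)

    return RunConfig(
        genotype_path=resolve(geno_file),
        phenotype_path=resolve(pheno_file),
        map_path=resolve(get("MAP_FILE")),
        ploidy=int(get_num("PLOIDY", 4, int)),
        genotype_format=(get("FORMAT") or "gwaspoly").lower(),
        gwas_model=(get("GWAS_MODEL") or "full").lower(),
        test_model=(get("TEST_MODEL") or "additive").lower(),
        significance=get_num("SIGNIFICANCE", 0.05),
        correction=(get("CORRECTION") or "bonferroni").lower(),
        n_best=int(get_num("N_BEST", 10, int)),
        filters=filters,
        engines=engines,
        ld_r2=get_num("LD_R2", 0.9),
        n_chromosomes=int(n_chroms_raw) if n_chroms_raw else None,
        name=path.stem.removesuffix(".config"),
    )


# ---------------------------------------------------------------------------
# genotype parsing
# ---------------------------------------------------------------------------

def _read_table(path: Path) -> pd.DataFrame:
    """Delimited table; separator (comma, tab or whitespace) chosen from the header."""
    with open(path) as fh:
        header = fh.readline()
    if "," in header:
        sep = ","
    elif "\t" in header:
        sep = "\t"
    else:
        sep = r"\s+"
    try:
        return pd.read_csv(path, sep=sep, engine="python", dtype=str,
                           keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse table {path}: {exc}") from exc


def _normalize_missing(s: str) -> str | None:
    return None if s.strip().upper() in MISSING_CODES else s.strip()


def read_map(path: str | Path) -> pd.DataFrame:
    """Read a marker map file (Marker, Chrom, Position, Ref, Alt)."""
    df = _read_table(Path(path))
    if df.shape[1] < 5:
        raise FormatError(f"map file {path} needs 5 columns, found {df.shape[1]}")
    df = df.iloc[:, :5]
    df.columns = MAP_COLUMNS
    return validate_marker_map(df)


def _dosage_from_acgt(call: str, ref: str, alt: str, ploidy: int, marker: str) -> float:
    norm = _normalize_missing(call)
    if norm is None:
        return np.nan
    norm = norm.upper()
    if len(norm) != ploidy:
        raise FormatError(
            f"call '{call}' for marker {marker} has {len(norm)} alleles, expected {ploidy}"
        )
    extra = set(norm) - {ref, alt}
    if extra:
        raise FormatError(
            f"call '{call}' for marker {marker} contains alleles {sorted(extra)} "
            f"outside ref={ref}/alt={alt}"
        )
    return float(norm.count(alt))


def _infer_ref_alt(calls: pd.Series) -> tuple[str, str]:
    """Majority allele -> ref (ties alphabetical); monomorphic -> next base as alt."""
    counts: dict[str, int] = {}
    for call in calls:
        norm = _normalize_missing(str(call))
        if norm is None:
            continue
        for a in norm.upper():
            counts[a] = counts.get(a, 0) + 1
    alleles = sorted(counts, key=lambda a: (-counts[a], a))
    if not alleles:
        raise FormatError("marker with all calls missing; cannot infer alleles")
    if len(alleles) > 2:
        raise FormatError(f"more than two alleles observed: {alleles}")
    ref = alleles[0]
    if len(alleles) == 2:
        return ref, alleles[1]
    alt = next(b for b in BASES if b != ref)
    return ref, alt


def _read_gwaspoly(path: Path, ploidy: int) -> GenotypeMatrix:
    df = _read_table(path)
    if df.shape[1] < 4:
        raise FormatError(f"{path}: gwaspoly table needs Marker, Chrom, Position + samples")
    cols_lower = [c.strip().lower() for c in df.columns]
    has_refalt = df.shape[1] >= 6 and cols_lower[3] == "ref" and cols_lower[4] == "alt"
    n_meta = 5 if has_refalt else 3
    meta = df.iloc[:, :n_meta].copy()
    calls = df.iloc[:, n_meta:]
    samples = [str(c) for c in calls.columns]
    markers = pd.DataFrame({
        "marker": meta.iloc[:, 0].astype(str),
        "chrom": meta.iloc[:, 1].astype(str),
        "pos": pd.to_numeric(meta.iloc[:, 2]),
    })
    if has_refalt:
        markers["ref"] = meta.iloc[:, 3].str.upper()
        markers["alt"] = meta.iloc[:, 4].str.upper()
    else:
        inferred = [_infer_ref_alt(calls.iloc[i]) for i in range(len(calls))]
        markers["ref"] = [r for r, _ in inferred]
        markers["alt"] = [a for _, a in inferred]
    dosage = np.empty(calls.shape, dtype=float)
    for i in range(calls.shape[0]):
        ref, alt = markers["ref"].iloc[i], markers["alt"].iloc[i]
        mid = markers["marker"].iloc[i]
        for j in range(calls.shape[1]):
            dosage[i, j] = _dosage_from_acgt(str(calls.iat[i, j]), ref, alt, ploidy, mid)
    return GenotypeMatrix(ploidy=ploidy, markers=markers, samples=samples, dosage=dosage)


def _read_vcf(path: Path, ploidy: int) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, dosage_rows = [], []
    for var in vcf:
        if len(var.REF) != 1 or len(var.ALT) != 1 or len(var.ALT[0]) != 1:
            warnings.warn(f"skipping non-biallelic-SNP record {var.ID or var.POS}")
            continue
        marker = var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}"
        row = np.empty(len(samples), dtype=float)
        for j, g in enumerate(var.genotypes):
            alleles = g[:-1]  # last element is the phased flag
            if any(a < 0 for a in alleles):
                row[j] = np.nan
                continue
            if len(alleles) != ploidy:
                raise FormatError(
                    f"VCF genotype ploidy {len(alleles)} at {marker} (sample "
                    f"{samples[j]}) inconsistent with configured ploidy {ploidy}"
                )
            if any(a > 1 for a in alleles):
                raise FormatError(f"multi-allelic genotype index at {marker}")
            row[j] = float(sum(alleles))
        rows.append((marker, str(var.CHROM), int(var.POS), var.REF, var.ALT[0]))
        dosage_rows.append(row)
    if not rows:
        raise FormatError(f"no usable biallelic SNP records in {path}")
    markers = pd.DataFrame(rows, columns=MAP_COLUMNS)
    return GenotypeMatrix(ploidy=ploidy, markers=markers, samples=samples,
                          dosage=np.vstack(dosage_rows))


def _dosage_cell(raw: str, ploidy: int, marker: str) -> float:
    norm = _normalize_missing(raw)
    if norm is None:
        return np.nan
    try:
        val = float(norm)
    except ValueError:
        raise FormatError(f"non-numeric dosage '{raw}' for marker {marker}") from None
    if not val.is_integer() or not (0 <= val <= ploidy):
        raise FormatError(f"dosage {raw} for marker {marker} outside 0..{ploidy}")
    return val


def _align_to_map(markers: pd.DataFrame, dosage: pd.DataFrame, ploidy: int,
                  path: Path) -> GenotypeMatrix:
    """Align a marker-indexed dosage frame with a map (set equality required)."""
    map_ids = set(markers["marker"])
    data_ids = set(dosage.index.astype(str))
    if map_ids != data_ids:
        raise FormatError(
            f"{path}: map/matrix marker mismatch "
            f"(only in map: {sorted(map_ids - data_ids)[:5]}; "
            f"only in matrix: {sorted(data_ids - map_ids)[:5]})"
        )
    dosage = dosage.loc[markers["marker"].tolist()]
    return GenotypeMatrix(
        ploidy=ploidy,
        markers=markers,
        samples=[str(c) for c in dosage.columns],
        dosage=dosage.to_numpy(dtype=float),
    )


def _read_matrix(path: Path, map_path: Path, ploidy: int) -> GenotypeMatrix:
    markers = read_map(map_path)
    df = _read_table(path)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: matrix format needs marker column + samples")
    df = df.set_index(df.columns[0])
    values = np.array(
        [[_dosage_cell(str(df.iat[i, j]), ploidy, str(df.index[i]))
          for j in range(df.shape[1])]
         for i in range(df.shape[0])]
    )
    parsed = pd.DataFrame(values, index=df.index.astype(str), columns=df.columns)
    return _align_to_map(markers, parsed, ploidy, path)


def _read_long_dosage(path: Path, map_path: Path, ploidy: int,
                      cols: tuple[str, str, str]) -> GenotypeMatrix:
    markers = read_map(map_path)
    df = _read_table(path)
    lower = {c.strip().lower(): c for c in df.columns}
    try:
        mcol, scol, gcol = (lower[c] for c in cols)
    except KeyError:
        raise FormatError(
            f"{path}: expected columns {cols}, found {list(df.columns)}"
        ) from None
    wide = df.pivot_table(index=mcol, columns=scol, values=gcol, aggfunc="first")
    wide = wide.map(lambda v: _dosage_cell(str(v), ploidy, "?") if v == v else np.nan)
    wide.index = wide.index.astype(str)
    wide.columns = [str(c) for c in wide.columns]
    return _align_to_map(markers, wide, ploidy, path)


def read_genotype(path: str | Path, format: str, map_path: str | Path | None = None,
                  ploidy: int = 4) -> GenotypeMatrix:
    """Read a genotype file in any of the five supported dialects.

    ``matrix``/``fitpoly``/``updog`` require ``map_path``; ``gwaspoly`` and
    ``vcf`` are self-contained.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"genotype file not found: {path}")
    format = format.lower()
    if format not in GENOTYPE_FORMATS:
        raise FormatError(f"unknown genotype format '{format}'")
    if format in ("matrix", "fitpoly", "updog"):
        if map_path is None:
            raise FormatError(f"format '{format}' requires a map file")
        map_path = Path(map_path)
        if not map_path.exists():
            raise FormatError(f"map file not found: {map_path}")
    if format == "gwaspoly":
        return _read_gwaspoly(path, ploidy)
    if format == "vcf":
        return _read_vcf(path, ploidy)
    if format == "matrix":
        return _read_matrix(path, map_path, ploidy)
    if format == "fitpoly":
        return _read_long_dosage(path, map_path, ploidy,
                                 ("markername", "samplename", "geno"))
    return _read_long_dosage(path, map_path, ploidy, ("snp", "ind", "geno"))


def write_gwaspoly(geno: GenotypeMatrix, path: str | Path) -> None:
    """Write the canonical dataset in the (self-contained) gwaspoly dialect."""
    out = geno.markers[MAP_COLUMNS].copy()
    out.columns = ["Marker", "Chrom", "Position", "Ref", "Alt"]
    acgt = geno.to_acgt_frame().reset_index(drop=True)
    pd.concat([out, acgt], axis=1).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# chromosome normalization
# ---------------------------------------------------------------------------

#: names longer than this are considered "too large" and renamed
MAX_CHROM_NAME_LEN = 10


def normalize_chromosomes(markers: pd.DataFrame, n: int | None = None
                          ) -> tuple[pd.DataFrame, dict[str, str]]:
    """Order contigs by size and rename unwieldy contig names.

    Contig size is approximated by the highest variant position on it.
    Contigs are sorted by that size, decreasing.  Names that are purely
    numeric or longer than :data:`MAX_CHROM_NAME_LEN` characters are
    replaced with ``contig<rank>`` (rank in the size ordering, 1-based).
    A boolean ``plot`` column flags the ``n`` largest contigs (all if
    ``n`` is None).  Markers are re-ordered by (contig rank, position,
    marker id).  Returns the new map and the old->new name mapping.
    """
    if len(markers) == 0:
        raise FormatError("cannot normalize an empty marker map")
    if n is not None and n < 1:
        raise FormatError(f"n_chromosomes must be >= 1, got {n}")
    m = validate_marker_map(markers)
    sizes = m.groupby("chrom")["pos"].max()
    order = sizes.sort_values(ascending=False, kind="mergesort")
    ranked = list(order.index)
    mapping: dict[str, str] = {}
    for rank, chrom in enumerate(ranked, start=1):
        if chrom.isdigit() or len(chrom) > MAX_CHROM_NAME_LEN:
            mapping[chrom] = f"contig{rank}"
        else:
            mapping[chrom] = chrom
    m["chrom"] = m["chrom"].map(mapping)
    rank_of = {mapping[c]: i for i, c in enumerate(ranked)}
    m["_rank"] = m["chrom"].map(rank_of)
    top = n if n is not None else len(ranked)
    m["plot"] = m["_rank"] < top
    m = m.sort_values(["_rank", "pos", "marker"], kind="mergesort")
    m = m.drop(columns="_rank").reset_index(drop=True)
    return m, mapping


def normalize_genotype_chromosomes(geno: GenotypeMatrix, n: int | None = None
                                   ) -> GenotypeMatrix:
    """Apply :func:`normalize_chromosomes` to a genotype matrix (rows re-ordered)."""
    new_map, _ = normalize_chromosomes(geno.markers, n)
    pos = {mid: i for i, mid in enumerate(geno.markers["marker"])}
    row_order = [pos[mid] for mid in new_map["marker"]]
    return GenotypeMatrix(
        ploidy=geno.ploidy,
        markers=new_map,
        samples=list(geno.samples),
        dosage=geno.dosage[row_order, :],
    )


# ---------------------------------------------------------------------------
# phenotype parsing
# ---------------------------------------------------------------------------

def read_phenotype(path: str | Path) -> PhenotypeTable:
    """Read a delimited phenotype table: sample id column + numeric trait columns.

    Non-numeric cells become missing (with a logged warning); duplicate
    sample ids are an error.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"phenotype file not found: {path}")
    df = _read_table(path)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: phenotype table needs sample id + >=1 trait column")
    samples = df.iloc[:, 0].astype(str).tolist()
    if len(set(samples)) != len(samples):
        dupes = df.iloc[:, 0][df.iloc[:, 0].duplicated()].tolist()[:5]
        raise FormatError(f"duplicate sample ids in phenotype: {dupes}")
    traits = pd.DataFrame(index=samples)
    for col in df.columns[1:]:
        numeric = pd.to_numeric(
            df[col].map(lambda v: None if _normalize_missing(str(v)) is None else v),
            errors="coerce",
        )
        n_coerced = int((numeric.isna() & df[col].map(
            lambda v: _normalize_missing(str(v)) is not None)).sum())
        if n_coerced:
            logger.warning("phenotype trait '%s': %d non-numeric cells set to missing",
                           col, n_coerced)
        traits[str(col)] = numeric.to_numpy()
    return PhenotypeTable(samples=samples, traits=traits)
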