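"""Reading, validation, harmonisation and QC of GWAS summary statistics.

The module turns delimited summary-statistics tables (GWAS-SSF-style
canonical headers, one row per variant) into validated
:class:`VariantAssociation` records, applies instrument QC (significance
threshold, confounder exclusion list, instrument-strength F filter, greedy
LD pruning against an optional user-supplied r² table), and harmonises
effect alleles across exposure, outcome and mediator traits into an
:class:`InstrumentSet` ready for the estimators in
:mod:`mrmediate.estimators` and :mod:`mrmediate.mediation`.

Conventions: coordinates are 1-based; every effect is per copy of the
effect allele; binary-trait effects are natural-log odds ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, NoInstrumentsError

__all__ = [
    "CANONICAL_COLUMNS",
    "LIPID_ASSOCIATED_SNPS",
    "VariantAssociation",
    "QCConfig",
    "HarmonizedInstrument",
    "InstrumentSet",
    "ReadResult",
    "read_sumstats",
    "associations_from_frame",
    "select_instruments",
    "f_statistic",
    "harmonize",
]

VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Canonical column order for summary-statistics tables.
CANONICAL_COLUMNS = (
    "variant_id",
    "chromosome",
    "base_pair_location",
    "effect_allele",
    "other_allele",
    "effect_allele_frequency",
    "beta",
    "standard_error",
    "p_value",
    "n",
)

#: Blood-lipid-associated variants excluded as potential confounder
#: instruments when studying platelet indices (a packaged exclusion list
#: replacing an online confounder-lookup service).
LIPID_ASSOCIATED_SNPS = frozenset(
    {
        "rs1260326",
        "rs964184",
        "rs10761731",
        "rs780093",
        "rs5130",
        "rs631106",
        "rs7896518",
    }
)


def f_statistic(beta: float, se: float) -> float:
    """Instrument-strength F statistic, ``(beta / se)**2``.

    Raises ``ValueError`` for non-positive ``se``.
    """
    if se <= 0:
        raise ValueError("standard error must be positive")
    return (beta / se) ** 2


@dataclass(frozen=True)
class VariantAssociation:
    """One variant's marginal association with one trait.

    ``beta`` is per effect-allele copy: log-odds for binary traits, SD
    units for continuous traits. Construction validates the invariants
    (positive SE, frequency strictly inside (0, 1), distinct single-base
    alleles, p-value in (0, 1]) and raises ``ValueError`` otherwise.
    """

    variant_id: str
    chromosome: str
    position: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pvalue: float
    n: int

    def __post_init__(self) -> None:
        if self.effect_allele not in VALID_ALLELES:
            raise ValueError(f"invalid effect allele {self.effect_allele!r}")
        if self.other_allele not in VALID_ALLELES:
            raise ValueError(f"invalid other allele {self.other_allele!r}")
        if self.effect_allele == self.other_allele:
            raise ValueError("identical effect and other allele")
        if not self.se > 0 or not math.isfinite(self.se):
            raise ValueError("non-positive SE")
        if not 0 < self.eaf < 1:
            raise ValueError("allele frequency outside (0, 1)")
        if not 0 < self.pvalue <= 1:
            raise ValueError("p-value outside (0, 1]")
        if self.position < 1:
            raise ValueError("position must be 1-based and positive")
        if self.n < 1:
            raise ValueError("sample size must be positive")
        if not math.isfinite(self.beta):
            raise ValueError("non-finite beta")

    @property
    def f_stat(self) -> float:
        return f_statistic(self.beta, self.se)

    @property
    def is_palindromic(self) -> bool:
        """True when the allele pair is A/T or C/G (strand-ambiguous)."""
        return _COMPLEMENT[self.effect_allele] == self.other_allele

    def flipped(self) -> "VariantAssociation":
        """The same association expressed for the other allele."""
        return replace(
            self,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            eaf=1.0 - self.eaf,
            beta=-self.beta,
        )


@dataclass(frozen=True)
class QCConfig:
    """Instrument-selection thresholds.

    Defaults follow the study design this package reproduces: genome-wide
    significance at p < 5e-10, pairwise LD independence at r² ≤ 1e-4, and
    the conventional weak-instrument cutoff F < 10. ``excluded_variants``
    is a user-supplied confounder list (see
    :data:`LIPID_ASSOCIATED_SNPS`). ``palindromic_eaf_window`` governs
    when strand-ambiguous variants are dropped during harmonisation.
    """

    p_threshold: float = 5e-10
    ld_r2_threshold: float = 1e-4
    f_threshold: float = 10.0
    excluded_variants: frozenset = frozenset()
    palindromic_eaf_window: float = 0.08

    def __post_init__(self) -> None:
        if not 0 < self.p_threshold < 1:
            raise ConfigurationError("p_threshold must lie in (0, 1)")
        for name in ("ld_r2_threshold", "f_threshold", "palindromic_eaf_window"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class HarmonizedInstrument:
    """Per-variant effects for exposure, outcome and optional mediators,
    all expressed for the same effect allele."""

    variant_id: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float
    eaf: float
    f_stat: float
    beta_mediators: tuple | None = None
    se_mediators: tuple | None = None


@dataclass
class InstrumentSet:
    """A harmonised, post-QC set of instruments for one trait pair
    (optionally with mediator columns for multivariable MR)."""

    exposure_name: str
    outcome_name: str
    mediator_names: tuple
    instruments: list
    qc_log: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.instruments)

    def __iter__(self):
        return iter(self.instruments)

    @property
    def n_snps(self) -> int:
        return len(self.instruments)

    @property
    def variant_ids(self) -> list:
        return [i.variant_id for i in self.instruments]

    @property
    def beta_exposure(self) -> np.ndarray:
        return np.array([i.beta_exposure for i in self.instruments])

    @property
    def se_exposure(self) -> np.ndarray:
        return np.array([i.se_exposure for i in self.instruments])

    @property
    def beta_outcome(self) -> np.ndarray:
        return np.array([i.beta_outcome for i in self.instruments])

    @property
    def se_outcome(self) -> np.ndarray:
        return np.array([i.se_outcome for i in self.instruments])

    @property
    def mediator_matrix(self) -> np.ndarray | None:
        """n_snps × n_mediators matrix of mediator effects, or None."""
        if not self.mediator_names:
            return None
        return np.array([i.beta_mediators for i in self.instruments])

    def subset(self, variant_ids: Iterable[str]) -> "InstrumentSet":
        keep = set(variant_ids)
        return InstrumentSet(
            self.exposure_name,
            self.outcome_name,
            self.mediator_names,
            [i for i in self.instruments if i.variant_id in keep],
            list(self.qc_log),
        )

    def drop(self, variant_ids: Iterable[str]) -> "InstrumentSet":
        bad = set(variant_ids)
        return self.subset(i.variant_id for i in self.instruments if i.variant_id not in bad)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for inst in self.instruments:
            row = {
                "variant_id": inst.variant_id,
                "beta_exposure": inst.beta_exposure,
                "se_exposure": inst.se_exposure,
                "beta_outcome": inst.beta_outcome,
                "se_outcome": inst.se_outcome,
                "eaf": inst.eaf,
                "f_stat": inst.f_stat,
            }
            for name, b, s in zip(
                self.mediator_names,
                inst.beta_mediators or (),
                inst.se_mediators or (),
            ):
                row[f"beta_{name}"] = b
                row[f"se_{name}"] = s
            rows.append(row)
        return pd.DataFrame(rows)


class ReadResult(NamedTuple):
    """Parsed records plus row-level problems (each tagged with its
    1-based line number in the source file)."""

    records: list
    problems: list


_NUMERIC_FIELDS = {
    "base_pair_location": int,
    "effect_allele_frequency": float,
    "beta": float,
    "standard_error": float,
    "p_value": float,
    "n": int,
}


def read_sumstats(
    path,
    column_map: Mapping[str, str] | None = None,
    delimiter: str | None = None,
) -> ReadResult:
    """Read a delimited summary-statistics table into validated records.

    Parameters
    ----------
    path
        Tab- or comma-delimited table with a header row. The delimiter is
        sniffed unless ``delimiter`` is given.
    column_map
        Optional mapping from the file's header names to the canonical
        ones in :data:`CANONICAL_COLUMNS`, for dialect tables.

    Returns
    -------
    ReadResult
        ``records`` holds every row that parsed and validated;
        ``problems`` holds one message per rejected row, with its line
        number. A missing mandatory column raises
        :class:`~mrmediate.errors.ConfigurationError`.
    """
    df = pd.read_csv(path, sep=delimiter, engine="python", dtype=str)
    if column_map:
        df = df.rename(columns=dict(column_map))
    for col in CANONICAL_COLUMNS:
        if col not in df.columns:
            raise ConfigurationError(f"missing required column '{col}'")

    records: list[VariantAssociation] = []
    problems: list[str] = []
    for i, row in enumerate(df[list(CANONICAL_COLUMNS)].itertuples(index=False)):
        line = i + 2  # header occupies line 1
        values = dict(zip(CANONICAL_COLUMNS, row))
        try:
            parsed = {}
            for name, raw in values.items():
                caster = _NUMERIC_FIELDS.get(name)
                if caster is None:
                    parsed[name] = str(raw).strip()
                else:
                    try:
                        parsed[name] = caster(float(raw))
                    except (TypeError, ValueError):
                        raise ValueError(f"unparseable value {raw!r} in column '{name}'")
            records.append(
                VariantAssociation(
                    variant_id=parsed["variant_id"],
                    chromosome=parsed["chromosome"],
                    position=parsed["base_pair_location"],
                    effect_allele=parsed["effect_allele"].upper(),
                    other_allele=parsed["other_allele"].upper(),
                    eaf=parsed["effect_allele_frequency"],
                    beta=parsed["beta"],
                    se=parsed["standard_error"],
                    pvalue=parsed["p_value"],
                    n=parsed["n"],
                )
            )
        except ValueError as exc:
            problems.append(f"line {line}: {exc}")
    return ReadResult(records, problems)


def associations_from_frame(df: pd.DataFrame) -> list:
    """Build records from an in-memory canonical-header DataFrame."""
    return [
        VariantAssociation(
            variant_id=str(t.variant_id),
            chromosome=str(t.chromosome),
            position=int(t.base_pair_location),
            effect_allele=str(t.effect_allele),
            other_allele=str(t.other_allele),
            eaf=float(t.effect_allele_frequency),
            beta=float(t.beta),
            se=float(t.standard_error),
            pvalue=float(t.p_value),
            n=int(t.n),
        )
        for t in df.itertuples(index=False)
    ]


def frame_from_associations(assocs: Sequence[VariantAssociation]) -> pd.DataFrame:
    """Inverse of :func:`associations_from_frame`."""
    return pd.DataFrame(
        {
            "variant_id": [a.variant_id for a in assocs],
            "chromosome": [a.chromosome for a in assocs],
            "base_pair_location": [a.position for a in assocs],
            "effect_allele": [a.effect_allele for a in assocs],
            "other_allele": [a.other_allele for a in assocs],
            "effect_allele_frequency": [a.eaf for a in assocs],
            "beta": [a.beta for a in assocs],
            "standard_error": [a.se for a in assocs],
            "p_value": [a.pvalue for a in assocs],
            "n": [a.n for a in assocs],
        }
    )


def _normalise_ld(ld_info) -> dict:
    """Accept a pairwise r² table as a DataFrame (variant_a, variant_b,
    r2) or a mapping keyed by id pairs; return a frozenset-keyed dict."""
    if ld_info is None:
        return {}
    if isinstance(ld_info, pd.DataFrame):
        cols = list(ld_info.columns[:3])
        return {
            frozenset((str(a), str(b))): float(r)
            for a, b, r in ld_info[cols].itertuples(index=False)
        }
    return {frozenset(map(str, pair)): float(r) for pair, r in dict(ld_info).items()}


def select_instruments(
    assocs: Sequence[VariantAssociation],
    config: QCConfig | None = None,
    ld_info=None,
):
    """Apply instrument QC and return ``(kept, qc_log)``.

    Filters are applied in order — significance, exclusion list,
    instrument strength, LD independence — and each removed variant is
    logged once with the first matching reason. LD pruning is greedy:
    variants are visited in ascending p-value order and dropped when
    their r² with an already-kept variant exceeds the threshold; pairs
    absent from ``ld_info`` are treated as independent.

    Raises :class:`~mrmediate.errors.NoInstrumentsError` when nothing
    survives.
    """
    if not assocs:
        raise ValueError("assocs must be non-empty")
    config = config or QCConfig()
    qc_log: list[tuple[str, str]] = []
    survivors: list[VariantAssociation] = []
    for a in assocs:
        if a.pvalue >= config.p_threshold:
            qc_log.append((a.variant_id, f"p-value {a.pvalue:.3g} above threshold"))
        elif a.variant_id in config.excluded_variants:
            qc_log.append((a.variant_id, "on excluded-variant (confounder) list"))
        elif a.f_stat < config.f_threshold:
            qc_log.append((a.variant_id, f"weak instrument (F = {a.f_stat:.2f})"))
        else:
            survivors.append(a)

    r2 = _normalise_ld(ld_info)
    dropped_ld: dict[str, str] = {}
    kept_ids: list[str] = []
    for a in sorted(survivors, key=lambda v: (v.pvalue, v.variant_id)):
        partner = next(
            (
                k
                for k in kept_ids
                if r2.get(frozenset((a.variant_id, k)), 0.0) > config.ld_r2_threshold
            ),
            None,
        )
        if partner is None:
            kept_ids.append(a.variant_id)
        else:
            dropped_ld[a.variant_id] = partner
    qc_log.extend(
        (vid, f"in LD with retained variant {partner}")
        for vid, partner in dropped_ld.items()
    )

    kept = [a for a in survivors if a.variant_id not in dropped_ld]
    if not kept:
        raise NoInstrumentsError("no instruments survive QC")
    return kept, qc_log


def _index_unique(assocs, qc_log):
    by_id: dict[str, VariantAssociation] = {}
    for a in assocs:
        if a.variant_id in by_id:
            qc_log.append((a.variant_id, "duplicate variant id (first kept)"))
        else:
            by_id[a.variant_id] = a
    return by_id


def _align(target: VariantAssociation, ref: VariantAssociation, window: float):
    """Express ``target`` for ``ref``'s effect allele.

    Returns ``(aligned, "")`` or ``(None, reason)``. Strand flips are
    resolved by base complementation; for palindromic reference alleles
    the orientation is decided by allele frequency, and variants too
    close to eaf 0.5 are rejected as ambiguous.
    """
    pair = (target.effect_allele, target.other_allele)
    if ref.is_palindromic:
        allowed = {
            (ref.effect_allele, ref.other_allele),
            (ref.other_allele, ref.effect_allele),
        }
        if pair not in allowed:
            return None, "irreconcilable alleles"
        if abs(target.eaf - 0.5) < window:
            return None, "ambiguous palindromic"
        same_side = (target.eaf - 0.5) * (ref.eaf - 0.5) > 0
        return (target if same_side else target.flipped()), ""

    direct = (ref.effect_allele, ref.other_allele)
    swapped = (ref.other_allele, ref.effect_allele)
    comp = (_COMPLEMENT[target.effect_allele], _COMPLEMENT[target.other_allele])
    if pair == direct or comp == direct:
        return target, ""
    if pair == swapped or comp == swapped:
        return target.flipped(), ""
    return None, "irreconcilable alleles"


def harmonize(
    exposure: Sequence[VariantAssociation],
    outcome: Sequence[VariantAssociation],
    mediators: Mapping[str, Sequence[VariantAssociation]] | None = None,
    *,
    palindromic_eaf_window: float = 0.08,
    exposure_name: str = "exposure",
    outcome_name: str = "outcome",
) -> InstrumentSet:
    """Harmonise effect alleles across traits into an InstrumentSet.

    Only variants present in every trait are used (two-sample design).
    Outcome and mediator effects are re-signed (beta → −beta,
    eaf → 1 − eaf) whenever their effect allele is the exposure's other
    allele; strand flips (A↔T, C↔G) are resolved by complementation
    before matching. Palindromic variants whose frequency lies within
    ``palindromic_eaf_window`` of 0.5 in any trait are dropped as
    ambiguous, otherwise aligned by frequency. Irreconcilable allele
    pairs are dropped and logged.
    """
    qc_log: list[tuple[str, str]] = []
    mediators = dict(mediators or {})
    exp_by_id = _index_unique(exposure, qc_log)
    out_by_id = _index_unique(outcome, qc_log)
    med_by_id = {name: _index_unique(assocs, qc_log) for name, assocs in mediators.items()}

    instruments: list[HarmonizedInstrument] = []
    for vid, exp in exp_by_id.items():
        if vid not in out_by_id:
            continue
        if any(vid not in table for table in med_by_id.values()):
            continue
        if exp.is_palindromic and abs(exp.eaf - 0.5) < palindromic_eaf_window:
            qc_log.append((vid, "ambiguous palindromic"))
            continue
        others = [out_by_id[vid]] + [med_by_id[name][vid] for name in mediators]
        aligned = []
        reason = None
        for other in others:
            res, why = _align(other, exp, palindromic_eaf_window)
            if res is None:
                reason = why
                break
            aligned.append(res)
        if reason is not None:
            qc_log.append((vid, reason))
            continue
        out_al, med_al = aligned[0], aligned[1:]
        instruments.append(
            HarmonizedInstrument(
                variant_id=vid,
                beta_exposure=exp.beta,
                se_exposure=exp.se,
                beta_outcome=out_al.beta,
                se_outcome=out_al.se,
                eaf=exp.eaf,
                f_stat=exp.f_stat,
                beta_mediators=tuple(m.beta for m in med_al) if med_al else None,
                se_mediators=tuple(m.se for m in med_al) if med_al else None,
            )
        )
    return InstrumentSet(
        exposure_name=exposure_name,
        outcome_name=outcome_name,
        mediator_names=tuple(mediators),
        instruments=instruments,
        qc_log=qc_log,
    )
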