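"""Translational-efficiency arithmetic for reporter constructs.

Translational efficiency (TE) of a construct is the quotient of specific
reporter-enzyme activity (nkat/mg) and relative transcript level
(normalized to 16S rRNA), computed per biological replicate and averaged.
The "TE" of an empty-vector strain is subtracted from every sample as a
background correction — after which near-zero efficiencies can legitimately
come out slightly negative. For comparative display, mutant TEs are
normalized to their matching unmutated control, whose normalized TE is
exactly 1 by construction.

Replicate spread is carried through the quotient, the subtraction and the
normalization by first-order (delta-method) error propagation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd


@dataclass(frozen=True)
class ReporterMeasurement:
    construct_id: str
    replicate: int
    specific_activity: float  # nkat/mg, >= 0
    transcript_level: float  # relative units, > 0 to be usable

    def __post_init__(self):
        if self.specific_activity < 0:
            raise ValueError(
                f"{self.construct_id} rep {self.replicate}: negative activity")


@dataclass
class TranslationalEfficiency:
    construct_id: str
    te_raw: float
    te_raw_sd: float
    te_corrected: float | None = None
    te_corrected_sd: float | None = None
    te_normalized: float | None = None
    te_normalized_sd: float | None = None
    negative_flag: bool = False  # set when a corrected/normalized TE < 0


def _mean_sd(values: list[float]) -> tuple[float, float]:
    n = len(values)
    mean = sum(values) / n
    if n < 2:
        return mean, 0.0
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return mean, math.sqrt(var)


def _raw_te(measurements: list[ReporterMeasurement]) -> tuple[float, float]:
    if not measurements:
        raise ValueError("no measurements given")
    ids = {m.construct_id for m in measurements}
    if len(ids) > 1:
        raise ValueError(f"mixed constructs in one sample: {sorted(ids)}")
    for m in measurements:
        if m.transcript_level <= 0:
            raise ValueError(
                f"{m.construct_id} rep {m.replicate}: zero transcript level")
    return _mean_sd([m.specific_activity / m.transcript_level
                     for m in measurements])


def translational_efficiency(
        sample: list[ReporterMeasurement],
        empty_vector: list[ReporterMeasurement]) -> TranslationalEfficiency:
    """Per-replicate activity/transcript quotient, background-subtracted.

    ``empty_vector`` holds the negative-control replicates; its mean TE is
    subtracted from the sample's. Uncertainties of the two means add in
    quadrature.
    """
    te_raw, sd_raw = _raw_te(sample)
    bg, bg_sd = _raw_te(empty_vector)
    te = TranslationalEfficiency(
        construct_id=sample[0].construct_id, te_raw=te_raw, te_raw_sd=sd_raw)
    te.te_corrected = te_raw - bg
    te.te_corrected_sd = math.hypot(sd_raw, bg_sd)
    te.negative_flag = te.te_corrected < 0
    return te


def normalize_to_reference(
        te: TranslationalEfficiency,
        reference: TranslationalEfficiency) -> TranslationalEfficiency:
    """Fill ``te_normalized`` = te_corrected / reference.te_corrected.

    The reference normalized against itself gives exactly 1 with zero
    propagated relative spread beyond its own.
    """
    if reference.te_corrected is None or reference.te_corrected <= 0:
        raise ValueError("reference construct must have positive corrected TE")
    if te.te_corrected is None:
        raise ValueError("corrected TE missing; run translational_efficiency")
    r = reference.te_corrected
    te.te_normalized = te.te_corrected / r
    if te is reference or te.construct_id == reference.construct_id:
        # self-normalization is exact by definition
        te.te_normalized = 1.0
        te.te_normalized_sd = 0.0
    else:
        rel_t = ((te.te_corrected_sd or 0.0) / te.te_corrected
                 if te.te_corrected else 0.0)
        rel_r = (reference.te_corrected_sd or 0.0) / r
        te.te_normalized_sd = abs(te.te_normalized) * math.hypot(rel_t, rel_r)
    te.negative_flag = te.te_normalized < 0
    return te


def efficiency_table(measurements: pd.DataFrame, reference: str,
                     control: str) -> pd.DataFrame:
    """TE table from a long-format measurement frame.

    Expects columns construct_id, replicate, activity, transcript. The
    ``control`` construct (empty vector) is subtracted from all, and all are
    normalized to ``reference``. Returns one row per construct with raw,
    corrected and normalized TE and propagated standard deviations.
    """
    required = {"construct_id", "replicate", "activity", "transcript"}
    missing = required - set(measurements.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")

    def rows_of(cid: str) -> list[ReporterMeasurement]:
        sub = measurements[measurements["construct_id"] == cid]
        if sub.empty:
            raise ValueError(f"construct {cid!r} not in measurements")
        return [ReporterMeasurement(cid, int(r.replicate), float(r.activity),
                                    float(r.transcript))
                for r in sub.itertuples()]

    control_rows = rows_of(control)
    tes = {}
    for cid in measurements["construct_id"].unique():
        if cid == control:
            continue
        tes[cid] = translational_efficiency(rows_of(cid), control_rows)
    ref_te = tes[reference] if reference in tes else None
    if ref_te is None:
        raise ValueError(f"reference {reference!r} not among constructs")
    out = []
    for cid, te in tes.items():
        normalize_to_reference(te, ref_te)
        out.append({"construct_id": cid,
                    "te_raw": te.te_raw, "te_raw_sd": te.te_raw_sd,
                    "te_corrected": te.te_corrected,
                    "te_corrected_sd": te.te_corrected_sd,
                    "te_normalized": te.te_normalized,
                    "te_normalized_sd": te.te_normalized_sd,
                    "negative": te.negative_flag})
    return pd.DataFrame(out)
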