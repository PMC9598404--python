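"""Ambient normalization of exhaled-air oxidative potential.

Ambient air oxidants (particles, NOx, ozone) reach the airways with the
inhaled air, so each exhaled-air measurement is divided by the oxidative
potential of the ambient air measured in the same session.  Both sides are in
pmol/L of air, so the ratio is dimensionless; a log10 transform makes the
right-skewed ratio approximately normal, and that log ratio is the OPEA value
carried through every downstream statistic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .io import Calibration, KineticTrace
from .kinetics import (
    DEFAULT_R2_THRESHOLD,
    DEFAULT_WINDOW,
    ReplicateError,
    aggregate_replicates,
    calibrate,
    fit_slope,
)

logger = logging.getLogger(__name__)

__all__ = ["OpeaRecord", "OpeaDomainError", "normalize", "build_opea_table", "opea_table_to_frame"]


class OpeaDomainError(ValueError):
    """A non-positive oxidative potential makes the log ratio undefined."""


@dataclass
class OpeaRecord:
    """Per-participant normalized oxidative potential.

    ``opea`` is log10(op_exhaled / op_ambient); it is None, with ``reason``
    set, when either side is non-positive or missing.
    """

    participant_id: str
    op_exhaled: float | None
    op_ambient: float | None
    ratio: float | None
    opea: float | None
    reason: str | None = None


def normalize(op_exhaled: float, op_ambient: float, participant_id: str = "") -> OpeaRecord:
    """Form the dimensionless exhaled/ambient ratio and its log10.

    Raises
    ------
    OpeaDomainError
        If either oxidative potential is non-positive; the message names the
        offending side.
    """
    if not op_ambient > 0:
        raise OpeaDomainError(
            f"participant {participant_id!r}: ambient oxidative potential "
            f"{op_ambient} is not positive"
        )
    if not op_exhaled > 0:
        raise OpeaDomainError(
            f"participant {participant_id!r}: exhaled oxidative potential "
            f"{op_exhaled} is not positive"
        )
    ratio = op_exhaled / op_ambient
    return OpeaRecord(
        participant_id=participant_id,
        op_exhaled=op_exhaled,
        op_ambient=op_ambient,
        ratio=ratio,
        opea=math.log10(ratio),
    )


def build_opea_table(
    traces: Sequence[KineticTrace],
    cal: Calibration,
    pairing: Mapping[str, tuple[Sequence[int], Sequence[int]]],
    window: tuple[float, float] = DEFAULT_WINDOW,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
    replicate_agg: str = "mean",
    ratio_estimator: str = "ratio_of_means",
) -> list[OpeaRecord]:
    """Compose fit → calibrate → pool replicates → normalize per participant.

    Parameters
    ----------
    pairing
        Maps participant id to ``(exhaled measurement ids, ambient
        measurement ids)``.  Ambient ids may be shared across participants
        (one ambient set per session).
    ratio_estimator
        ``"ratio_of_means"`` (default) pools replicates on each side before
        taking the ratio — the lower-variance estimator; ``"mean_of_ratios"``
        pairs replicates positionally and averages the per-pair log ratios
        (requires equal replicate counts on both sides).

    Participants whose OPEA is undefined (non-positive pooled value, or no
    QC-passing replicate) are retained with ``opea`` missing and a reason
    code.  Ids referenced by the pairing but absent from ``traces`` raise.
    """
    by_id = {tr.measurement_id: tr for tr in traces}
    dangling = sorted(
        {mid for exh, amb in pairing.values() for mid in (*exh, *amb)} - set(by_id)
    )
    if dangling:
        raise KeyError(f"pairing references missing measurement ids: {dangling}")

    def pooled(ids: Sequence[int]) -> float:
        ops = [
            calibrate(fit_slope(by_id[mid], window), cal, r2_threshold, replicate_index=i)
            for i, mid in enumerate(ids)
        ]
        return aggregate_replicates(ops, how=replicate_agg)

    records: list[OpeaRecord] = []
    n_undefined = 0
    for pid, (exh_ids, amb_ids) in pairing.items():
        try:
            if ratio_estimator == "ratio_of_means":
                op_e = pooled(exh_ids)
                op_a = pooled(amb_ids)
                records.append(normalize(op_e, op_a, participant_id=pid))
            elif ratio_estimator == "mean_of_ratios":
                if len(exh_ids) != len(amb_ids):
                    raise ValueError(
                        f"participant {pid!r}: mean_of_ratios requires equal replicate "
                        f"counts ({len(exh_ids)} vs {len(amb_ids)})"
                    )
                pairs = [
                    normalize(pooled([e]), pooled([a]), participant_id=pid)
                    for e, a in zip(exh_ids, amb_ids)
                ]
                opea = sum(r.opea for r in pairs) / len(pairs)
                records.append(
                    OpeaRecord(
                        participant_id=pid,
                        op_exhaled=sum(r.op_exhaled for r in pairs) / len(pairs),
                        op_ambient=sum(r.op_ambient for r in pairs) / len(pairs),
                        ratio=10.0**opea,
                        opea=opea,
                    )
                )
            else:
                raise ValueError(f"unknown ratio_estimator {ratio_estimator!r}")
        except (OpeaDomainError, ReplicateError) as exc:
            n_undefined += 1
            records.append(
                OpeaRecord(
                    participant_id=pid,
                    op_exhaled=None,
                    op_ambient=None,
                    ratio=None,
                    opea=None,
                    reason=str(exc),
                )
            )
    if n_undefined:
        logger.info("OPEA undefined for %d of %d participants", n_undefined, len(pairing))
    return records


def opea_table_to_frame(records: Sequence[OpeaRecord]) -> pd.DataFrame:
    """Tabulate OPEA records, one row per participant."""
    return pd.DataFrame(
        {
            "participant_id": [r.participant_id for r in records],
            "op_exhaled": [r.op_exhaled for r in records],
            "op_ambient": [r.op_ambient for r in records],
            "ratio": [r.ratio for r in records],
            "opea": [r.opea for r in records],
            "reason": [r.reason for r in records],
        }
    )
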