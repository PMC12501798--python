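"""Processing-efficiency trait suite computed from per-sample object counts.

For a processed pod sample with per-class counts (IP = intact pods,
WS = whole seeds, SS = split-seed detections) the split-seed count enters
every total as SS/2, on the assumption that each detected split is one of
two halves of a single seed. With class proportions P_c = count_c / total:

* ``PE  = P_WS + P_SS`` — processing efficiency, the fraction of seed
  objects freed from their pods;
* ``PE_WS = P_WS + P_SS * (1 - lambda)`` — PE penalising splits when whole
  seed is the desired end product;
* ``PE_SS = P_WS * (1 - lambda) + P_SS`` — PE penalising whole seeds when
  splits are desired;
* ``DE = SS / (WS + SS)`` — dehulling efficiency among freed seeds;
* ``NOPGS`` / ``NOPGM`` — objects per gram of input pod sample / of
  processed mixture.

The penalty weight lambda lies in [0, 1]; lambda = 0 disables the penalty
(PE_WS = PE_SS = PE) and the identity ``PE_WS + PE_SS = (2 - lambda) * PE``
holds for every lambda and count vector.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

DEFAULT_LAMBDA = 0.6


@dataclass(frozen=True)
class SeedObjectCounts:
    """Per-class object counts for one sample, with the SS/2 rule applied."""

    n_ip: float
    n_ws: float
    n_ss_raw: float

    def __post_init__(self) -> None:
        if min(self.n_ip, self.n_ws, self.n_ss_raw) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def ss_effective(self) -> float:
        """Split-seed contribution to the total: raw detections / 2 (fractional)."""
        return self.n_ss_raw / 2.0

    @property
    def total(self) -> float:
        return self.n_ip + self.n_ws + self.ss_effective

    @property
    def is_degenerate(self) -> bool:
        return self.total == 0


@dataclass(frozen=True)
class SeedTraits:
    p_ip: float
    p_ws: float
    p_ss: float
    pe: float
    pe_ws: float
    pe_ss: float
    lambda_: float
    de: float | None
    nopgs: float
    nopgm: float | None
    total: float


def dehulling_efficiency(ws: float, ss: float) -> float:
    """DE = ss / (ws + ss), from counts or masses of whole and split seeds."""
    if ws < 0 or ss < 0:
        raise ValueError("ws and ss must be non-negative")
    if ws + ss == 0:
        raise ValueError("DE undefined when ws + ss = 0")
    return ss / (ws + ss)


def compute_traits(
    counts: SeedObjectCounts,
    pod_mass_g: float,
    mixture_mass_g: float | None = None,
    lambda_: float = DEFAULT_LAMBDA,
) -> SeedTraits:
    """Derive the full trait vector for one sample.

    ``mixture_mass_g`` may be None or 0, in which case NOPGM is undefined
    (None). DE is None when no seeds were freed (WS + SS = 0). A sample
    with zero total has no defined proportions and raises; callers flag and
    exclude such samples.
    """
    if not 0.0 <= lambda_ <= 1.0:
        raise ValueError(f"lambda must lie in [0, 1], got {lambda_}")
    if pod_mass_g <= 0:
        raise ValueError(f"pod_mass_g must be > 0, got {pod_mass_g}")
    total = counts.total
    if total == 0:
        raise ValueError("traits undefined for a sample with zero objects")

    p_ip = counts.n_ip / total
    p_ws = counts.n_ws / total
    p_ss = counts.ss_effective / total
    pe = p_ws + p_ss
    pe_ws = p_ws + p_ss * (1.0 - lambda_)
    pe_ss = p_ws * (1.0 - lambda_) + p_ss
    de = None
    if counts.n_ws + counts.ss_effective > 0:
        de = dehulling_efficiency(counts.n_ws, counts.ss_effective)
    nopgm = None
    if mixture_mass_g is not None and mixture_mass_g > 0:
        nopgm = total / mixture_mass_g
    return SeedTraits(
        p_ip=p_ip, p_ws=p_ws, p_ss=p_ss,
        pe=pe, pe_ws=pe_ws, pe_ss=pe_ss, lambda_=lambda_,
        de=de, nopgs=total / pod_mass_g, nopgm=nopgm, total=total,
    )


def class_percentages(n_ip: float, n_ws: float, n_ss: float, halve_ss: bool = False):
    """Class composition percentages of an annotation or detection tally.

    ``halve_ss=False`` reports the composition of raw box counts (the
    convention for annotation bookkeeping); ``halve_ss=True`` applies the
    SS/2 rule first (the convention for sample proportions).
    """
    ss = n_ss / 2.0 if halve_ss else n_ss
    total = n_ip + n_ws + ss
    if total == 0:
        raise ValueError("no objects")
    return {
        "IP": 100.0 * n_ip / total,
        "WS": 100.0 * n_ws / total,
        "SS": 100.0 * ss / total,
        "total": total,
    }


@dataclass
class TraitTable:
    """Join of sample metadata, counts, and traits; one row per sample."""

    frame: pd.DataFrame
    n_degenerate: int = 0
    degenerate_ids: list = field(default_factory=list)


def build_trait_table(
    samples: pd.DataFrame,
    counts: dict[str, SeedObjectCounts],
    lambda_: float = DEFAULT_LAMBDA,
) -> TraitTable:
    """Compute traits for every sample with counts; flag degenerate samples.

    ``samples`` must carry the sample-table columns; ``counts`` maps
    sample_id -> SeedObjectCounts. Samples whose total is zero are excluded
    from the table (downstream models cannot use them) and reported.
    """
    rows = []
    degenerate = []
    for _, s in samples.iterrows():
        sid = s["sample_id"]
        if sid not in counts:
            continue
        c = counts[sid]
        if c.is_degenerate:
            degenerate.append(sid)
            continue
        t = compute_traits(
            c,
            pod_mass_g=s["legume_fruit_pod_mass_g"],
            mixture_mass_g=s["processed_mixture_mass_g"],
            lambda_=lambda_,
        )
        rows.append(
            {
                "sample_id": sid,
                "variety": s["variety"],
                "processing_method": s["processing_method"],
                "nominal_mass_g": s["nominal_mass_g"],
                "legume_fruit_pod_mass_g": s["legume_fruit_pod_mass_g"],
                "processed_mixture_mass_g": s["processed_mixture_mass_g"],
                "replicate": s["replicate"],
                "n_ip": c.n_ip,
                "n_ws": c.n_ws,
                "n_ss_raw": c.n_ss_raw,
                "ss_effective": c.ss_effective,
                "total_objects": c.total,
                "p_ip": t.p_ip,
                "p_ws": t.p_ws,
                "p_ss": t.p_ss,
                "pe": t.pe,
                "pe_ws": t.pe_ws,
                "pe_ss": t.pe_ss,
                "de": math.nan if t.de is None else t.de,
                "nopgs": t.nopgs,
                "nopgm": math.nan if t.nopgm is None else t.nopgm,
                "lambda": lambda_,
            }
        )
    return TraitTable(pd.DataFrame(rows), len(degenerate), degenerate)
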