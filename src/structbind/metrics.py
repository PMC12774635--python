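"""Allele-preference metrics for paired reference/alternative TF-DNA models.

Four scores quantify how a single-nucleotide change tilts predicted
binding, all oriented so that positive values mean reference-allele
preference (the PBS sign convention):

* ``ddg_sym``      — (ddG_ref->alt - ddG_alt->ref) / 2, kcal/mol.  The
  forward mutation destabilising (+) and the reverse stabilising (-) both
  indicate the reference allele binds better.
* ``d_interface``  — Interface_alt - Interface_ref, kcal/mol.  FoldX
  interaction energies are more negative when stronger, so a positive
  difference means a weaker alternative-allele interface.
* ``d_iptm``       — ipTM_ref - ipTM_alt, unitless in [-1, 1].
* ``ddg_max_iptm`` — the ddG of whichever model the predictor is more
  confident about (higher ipTM); ties take the mean of both, preserving
  antisymmetry under allele swap.

An optional PAE-derived interface confidence (ipSAE) and a qualitative
consensus call over the three core metrics complete the set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .model_io import (
    AllelePair,
    ConfidenceSummary,
    EnergyRecord,
    PaeMatrix,
    StructureModel,
)
from .sasa import SasaParams, binding_site_shift

__all__ = [
    "MetricSet",
    "DEFAULT_CONSENSUS_FLOORS",
    "ddg_sym",
    "delta_interface",
    "delta_iptm",
    "ddg_max_iptm",
    "ipsae_scores",
    "consensus_call",
    "score_pair",
]

#: Minimum magnitudes a metric must clear before the consensus treats it as
#: a real directional signal (kcal/mol for the energies, ipTM units for
#: d_iptm).  Deliberately user-visible configuration.
DEFAULT_CONSENSUS_FLOORS: dict[str, float] = {
    "ddg_sym": 0.5,
    "d_interface": 0.5,
    "d_iptm": 0.02,
}

CORE_METRICS = ("ddg_sym", "d_interface", "d_iptm")


@dataclass(frozen=True)
class MetricSet:
    """Derived scores for one allele pair; absent components stay ``None``."""

    pair_id: str
    ddg_sym: float | None = None
    d_interface: float | None = None
    d_iptm: float | None = None
    ddg_max_iptm: float | None = None
    sasa_cor: float | None = None
    ipsae_mean: float | None = None
    ipsae_max: float | None = None
    consensus: str | None = None


def ddg_sym(rec: EnergyRecord) -> float | None:
    """Symmetric ddG: half the difference of forward and reverse mutations."""
    if rec.ddg_fwd is None or rec.ddg_rev is None:
        return None
    return (rec.ddg_fwd - rec.ddg_rev) / 2.0


def delta_interface(rec: EnergyRecord) -> float | None:
    """Interface-energy difference, alternative minus reference."""
    if rec.interface_alt is None or rec.interface_ref is None:
        return None
    return rec.interface_alt - rec.interface_ref


def delta_iptm(conf_ref: ConfidenceSummary, conf_alt: ConfidenceSummary) -> float:
    """ipTM difference, reference minus alternative."""
    return conf_ref.iptm - conf_alt.iptm


def ddg_max_iptm(
    rec: EnergyRecord,
    conf_ref: ConfidenceSummary,
    conf_alt: ConfidenceSummary,
) -> float | None:
    """ddG of the higher-confidence model of the pair.

    Higher reference ipTM selects the forward (ref->alt) ddG, higher
    alternative ipTM the reverse; an exact tie averages the two.
    """
    if conf_ref.iptm > conf_alt.iptm:
        return rec.ddg_fwd
    if conf_alt.iptm > conf_ref.iptm:
        return rec.ddg_rev
    if rec.ddg_fwd is None or rec.ddg_rev is None:
        return None
    return (rec.ddg_fwd + rec.ddg_rev) / 2.0


# ---------------------------------------------------------------------------
# ipSAE
# ---------------------------------------------------------------------------

def _tm_d0(n: int) -> float:
    """TM-score distance scale for an effective alignment of n residues."""
    n_eff = max(n, 19)
    return max(1.0, 1.24 * (n_eff - 15) ** (1.0 / 3.0) - 1.8)


def _ipsae_directed(pae: np.ndarray, rows: np.ndarray, cols: np.ndarray, cutoff: float) -> float:
    """ipSAE for the ordered chain pair (rows -> cols).

    Per aligned residue i, only cross-chain entries with PAE below the
    cutoff contribute; the TM-style distance scale d0 is set from the
    number of contributing residues for that i.  The pair score is the
    best per-residue value; no residue with any sub-cutoff entry gives 0.
    """
    block = pae[np.ix_(rows, cols)]
    best = 0.0
    for i in range(block.shape[0]):
        vals = block[i][block[i] < cutoff]
        if vals.size == 0:
            continue
        d0 = _tm_d0(vals.size)
        score = float(np.mean(1.0 / (1.0 + (vals / d0) ** 2)))
        best = max(best, score)
    return best


def ipsae_scores(
    pae: PaeMatrix,
    model: StructureModel,
    pae_cutoff: float = 10.0,
) -> tuple[float, float]:
    """(mean ipSAE, max ipSAE) over the chains of a model.

    The mean score averages, over every unordered chain pair, the larger
    of the two directed pair scores; the max score is the largest directed
    score among protein-DNA pairs only.
    """
    if len(model.chains) < 2:
        raise ValueError("ipSAE needs at least 2 chains")
    if pae.n != model.n_residues:
        raise ValueError(
            f"PAE dimension {pae.n} != model residue count {model.n_residues}"
        )
    # concatenated residue order: chains in model order, positions ascending
    index: dict[str, np.ndarray] = {}
    start = 0
    for cid, _kind in model.chains:
        n = len(model.chain_residues(cid))
        index[cid] = np.arange(start, start + n)
        start += n
    kinds = model.chain_kinds
    chain_ids = [cid for cid, _ in model.chains]
    pair_maxima = []
    protein_dna = []
    for i, a in enumerate(chain_ids):
        for b in chain_ids[i + 1:]:
            fwd = _ipsae_directed(pae.values, index[a], index[b], pae_cutoff)
            rev = _ipsae_directed(pae.values, index[b], index[a], pae_cutoff)
            m = max(fwd, rev)
            pair_maxima.append(m)
            if {kinds[a], kinds[b]} == {"protein", "dna"}:
                protein_dna.append(m)
    mean_ipsae = float(np.mean(pair_maxima))
    max_ipsae = float(max(protein_dna)) if protein_dna else 0.0
    return mean_ipsae, max_ipsae


# ---------------------------------------------------------------------------
# Consensus and composition
# ---------------------------------------------------------------------------

def consensus_call(
    m: MetricSet,
    magnitude_floors: dict[str, float] | None = None,
) -> str | None:
    """Qualitative consensus over ddg_sym, d_interface and d_iptm.

    All available core metrics clearing their floors with one common sign
    give a directional call (``ref_pref`` / ``alt_pref``); all sitting
    within their floors give ``no_preference``; any other combination is
    ``ambiguous``.  Fewer than two available core metrics: no call.
    """
    floors = dict(DEFAULT_CONSENSUS_FLOORS)
    if magnitude_floors:
        floors.update(magnitude_floors)
    values = {name: getattr(m, name) for name in CORE_METRICS}
    present = {k: v for k, v in values.items() if v is not None}
    if len(present) < 2:
        return None
    above = {k: v for k, v in present.items() if abs(v) > floors[k]}
    if not above:
        return "no_preference"
    if len(above) == len(present):
        signs = {math.copysign(1.0, v) for v in above.values()}
        if len(signs) == 1:
            return "ref_pref" if signs.pop() > 0 else "alt_pref"
    return "ambiguous"


def score_pair(
    pair: AllelePair,
    conf_ref: ConfidenceSummary,
    conf_alt: ConfidenceSummary,
    energies: EnergyRecord | None = None,
    model_ref: StructureModel | None = None,
    model_alt: StructureModel | None = None,
    pae_ref: PaeMatrix | None = None,
    sasa_params: SasaParams | None = None,
    shift_threshold: float = 0.8,
    pae_cutoff: float = 10.0,
    magnitude_floors: dict[str, float] | None = None,
) -> MetricSet:
    """Assemble the full metric set for one allele pair.

    Confidence summaries are the minimum input; energy records add the
    FoldX-derived metrics, paired structures add the DNA SASA correlation,
    and a PAE matrix for the reference model adds ipSAE.  Inputs carrying
    a different pair_id than ``pair`` are rejected.
    """
    if energies is not None and energies.pair_id != pair.pair_id:
        raise ValueError(
            f"energy record pair_id {energies.pair_id!r} != {pair.pair_id!r}"
        )
    m = MetricSet(pair_id=pair.pair_id, d_iptm=delta_iptm(conf_ref, conf_alt))
    if energies is not None:
        m = replace(
            m,
            ddg_sym=ddg_sym(energies),
            d_interface=delta_interface(energies),
            ddg_max_iptm=ddg_max_iptm(energies, conf_ref, conf_alt),
        )
    if model_ref is not None and model_alt is not None:
        shift = binding_site_shift(
            model_ref, model_alt, sasa_params, threshold=shift_threshold
        )
        m = replace(m, sasa_cor=shift.rho)
    if pae_ref is not None and model_ref is not None:
        mean_i, max_i = ipsae_scores(pae_ref, model_ref, pae_cutoff)
        m = replace(m, ipsae_mean=mean_i, ipsae_max=max_i)
    return replace(m, consensus=consensus_call(m, magnitude_floors))


# ---------------------------------------------------------------------------
# Serialization: one TSV row per pair, nulls as empty fields
# ---------------------------------------------------------------------------

_TSV_FIELDS = (
    "pair_id", "ddg_sym", "d_interface", "d_iptm", "ddg_max_iptm",
    "sasa_cor", "ipsae_mean", "ipsae_max", "consensus",
)


def write_metric_sets(metric_sets, path) -> None:
    lines = ["\t".join(_TSV_FIELDS)]
    for m in metric_sets:
        row = []
        for f in _TSV_FIELDS:
            v = getattr(m, f)
            if v is None:
                row.append("")
            elif isinstance(v, float):
                row.append(f"{v:.6g}")
            else:
                row.append(str(v))
        lines.append("\t".join(row))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_metric_sets(path) -> list[MetricSet]:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    header = lines[0].split("\t")
    if header != list(_TSV_FIELDS):
        raise ValueError(f"unexpected metric TSV header {header}")
    out = []
    for ln in lines[1:]:
        vals = dict(zip(_TSV_FIELDS, ln.split("\t")))
        kwargs = {"pair_id": vals["pair_id"]}
        for f in _TSV_FIELDS[1:-1]:
            kwargs[f] = float(vals[f]) if vals.get(f) else None
        kwargs["consensus"] = vals.get("consensus") or None
        out.append(MetricSet(**kwargs))
    return out
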