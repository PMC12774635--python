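"""Synthetic fixture cohorts with statistically controlled ground truth.

Every external artifact the pipeline consumes can be generated here at toy
scale: idealized B-DNA duplex structures with a pseudo-atom protein blob
packed against a chosen binding window, model-confidence JSONs, FoldX-style
``Dif_``/``Interaction_`` fxout files, and a PBS table.  A latent per-pair
preference effect ``delta`` drives all channels coherently — positive delta
means reference-allele preference in every output, mirroring the sign
structure of real SNP-SELEX benchmarks — and a manifest records the planted
truths so recovery can be tested end to end.

The structures are deliberately schematic (four pseudo-atoms per
nucleotide, one per protein residue): enough to produce non-degenerate
per-nucleotide SASA footprints and plantable binding-site shifts, with no
claim of biophysical realism.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .model_io import (
    AllelePair,
    Atom,
    ConfidenceSummary,
    EnergyRecord,
    Residue,
    StructureModel,
    write_pbs_table,
    write_structure_pdb,
)
from .oligo_windows import reverse_complement

__all__ = [
    "SimulationParams",
    "PairFixture",
    "build_bdna_duplex",
    "place_tf_blob",
    "build_pae",
    "simulate_pair",
    "simulate_cohort",
    "write_dif_fxout",
    "write_interaction_fxout",
]

RISE = 3.4       # helix rise per base pair, angstroms
TWIST = 36.0     # helix twist per base pair, degrees
STRAND_OFFSET = 140.0  # angular offset of the second strand, degrees

#: pseudo-atom layout per nucleotide: (name, element, radius from axis)
_NT_ATOMS = (("P", "P", 9.4), ("C1'", "C", 7.0), ("N1", "N", 4.5), ("C2", "C", 2.5))


@dataclass(frozen=True)
class SimulationParams:
    """Cohort generator settings.

    The defaults define the standard study conditions used throughout the
    test suite: 400 pairs, half with no true effect, unit effect magnitude
    and unit channel couplings, channel noise of 0.1 sd, and half the
    true-effect pairs carrying a 10-bp binding-site displacement.
    """

    seed: int
    n_pairs: int = 400
    duplex_len: int = 40
    variant_offset: int = 21
    null_fraction: float = 0.5
    effect_magnitude: float = 1.0
    shift_prob: float = 0.5
    shift_bp: int = 10
    site_width: int = 10
    noise_sd_iptm: float = 0.1
    noise_sd_ddg: float = 0.1
    noise_sd_interface: float = 0.1
    noise_sd_pbs: float = 0.1
    c_iptm: float = 1.0
    c_ddg: float = 1.0
    c_interface: float = 1.0
    c_pbs: float = 1.0
    iptm_base: float = 0.5
    interface_base: float = -10.0
    write_structures: bool = True

    def __post_init__(self) -> None:
        for name in ("null_fraction", "shift_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in (
            "noise_sd_iptm", "noise_sd_ddg", "noise_sd_interface", "noise_sd_pbs"
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.duplex_len < self.variant_offset:
            raise ValueError("duplex_len must be >= variant_offset")


@dataclass
class PairFixture:
    """One generated allele pair with its latent truth."""

    pair: AllelePair
    conf_ref: ConfidenceSummary
    conf_alt: ConfidenceSummary
    energies: EnergyRecord
    model_ref: StructureModel | None
    model_alt: StructureModel | None
    delta: float
    shifted: bool
    site_center_ref: int
    site_center_alt: int


# ---------------------------------------------------------------------------
# Structures
# ---------------------------------------------------------------------------

def build_bdna_duplex(
    seq: str,
    chain_ids: tuple[str, str] = ("B", "C"),
    model_id: str = "duplex",
) -> StructureModel:
    """Idealized B-DNA duplex from a forward-strand sequence.

    Two antiparallel chains on a common helix axis (3.4-angstrom rise,
    36-degree twist); the second chain carries the reverse complement,
    its residue k pairing with forward residue L+1-k at the same height.
    Deterministic: the same sequence always gives identical coordinates.
    """
    seq = seq.upper()
    if len(seq) < 4:
        raise ValueError("duplex needs length >= 4")
    if not set(seq) <= set("ACGT"):
        raise ValueError(f"invalid bases {sorted(set(seq) - set('ACGT'))}")
    rc = reverse_complement(seq)
    L = len(seq)
    b1, b2 = chain_ids
    residues: list[Residue] = []
    atoms: list[Atom] = []

    def add_nt(chain: str, pos: int, base: str, angle_deg: float, z: float) -> None:
        residues.append(Residue(chain, pos, "D" + base))
        a = math.radians(angle_deg)
        for name, element, radius in _NT_ATOMS:
            atoms.append(
                Atom(chain, pos, name, element,
                     radius * math.cos(a), radius * math.sin(a), z)
            )

    for i, base in enumerate(seq):  # forward strand, 5'->3'
        add_nt(b1, i + 1, base, i * TWIST, i * RISE)
    for k, base in enumerate(rc):   # reverse strand; pairs with fwd L-k
        j = L - 1 - k
        add_nt(b2, k + 1, base, j * TWIST + STRAND_OFFSET, j * RISE)
    return StructureModel(
        model_id=model_id,
        chains=[(b1, "dna"), (b2, "dna")],
        residues=residues,
        atoms=atoms,
    )


def place_tf_blob(
    duplex: StructureModel,
    site_center: int,
    site_width: int = 10,
    chain_id: str = "A",
    model_id: str | None = None,
) -> StructureModel:
    """Add a protein pseudo-atom blob packed against a duplex window.

    The blob wraps both strands over ``site_width`` base pairs centred on
    ``site_center`` (1-based forward-strand position), occluding the
    covered nucleotides so their SASA drops below the uncovered baseline.
    Moving the centre therefore moves the dip in the per-nucleotide SASA
    profile — the planted binding-site shift.
    """
    dna = duplex.dna_chain_ids()
    if len(dna) != 2:
        raise ValueError("duplex must have exactly 2 DNA chains")
    L = len(duplex.chain_residues(dna[0]))
    half = site_width // 2
    lo, hi = site_center - half, site_center + half - (1 - site_width % 2)
    if lo < 1 or hi > L:
        raise ValueError(
            f"site window [{lo}, {hi}] outside duplex of length {L}"
        )
    residues = list(duplex.residues)
    atoms = list(duplex.atoms)
    pos = 0
    for p in range(lo, hi + 1):
        i = p - 1
        z = i * RISE
        for base_angle in (i * TWIST, i * TWIST + STRAND_OFFSET):
            for off in (-28.0, 0.0, 28.0):
                a = math.radians(base_angle + off)
                pos += 1
                residues.append(Residue(chain_id, pos, "GLY"))
                atoms.append(
                    Atom(chain_id, pos, "CA", "C",
                         12.0 * math.cos(a), 12.0 * math.sin(a), z)
                )
    return StructureModel(
        model_id=model_id or f"{duplex.model_id}_blob{site_center}",
        chains=[(chain_id, "protein")] + list(duplex.chains),
        residues=residues,
        atoms=atoms,
    )


def build_pae(
    model: StructureModel,
    interchain_error: float = 5.0,
    intrachain_error: float = 2.0,
) -> np.ndarray:
    """Schematic PAE matrix aligned to a model's concatenated residues."""
    sizes = [len(model.chain_residues(cid)) for cid, _ in model.chains]
    n = sum(sizes)
    pae = np.full((n, n), float(interchain_error))
    start = 0
    for s in sizes:
        pae[start:start + s, start:start + s] = intrachain_error
        start += s
    np.fill_diagonal(pae, 0.0)
    return pae


# ---------------------------------------------------------------------------
# fxout writers (the exact dialects model_io parses)
# ---------------------------------------------------------------------------

def write_dif_fxout(path: str | Path, model_name: str, energies: list[float]) -> None:
    """Write a BuildModel ``Dif_*.fxout`` file, one row per run."""
    lines = [
        "FoldX output file",
        "",
        "Pdb\ttotal energy\tBackbone Hbond\tSidechain Hbond\tVan der Waals",
        ]
    for k, e in enumerate(energies, start=1):
        lines.append(f"{model_name}_{k}.pdb\t{e:.6f}\t0\t0\t0")
    Path(path).write_text("\n".join(lines) + "\n")


def write_interaction_fxout(
    path: str | Path,
    model_name: str,
    rows: list[tuple[str, str, float]],
) -> None:
    """Write an AnalyseComplex ``Interaction_*.fxout`` file."""
    lines = [
        "FoldX interaction output",
        "",
        "Pdb\tGroup1\tGroup2\tIntraclashesGroup1\tIntraclashesGroup2\t"
        "Interaction Energy\tBackbone Hbond",
    ]
    for c1, c2, e in rows:
        lines.append(f"{model_name}.pdb\t{c1}\t{c2}\t0\t0\t{e:.6f}\t0")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

def _pbs_pvalue(pbs: float, noise_sd: float) -> float:
    """Two-sided normal-tail p under the known null noise model."""
    if noise_sd == 0.0:
        return 1.0 if pbs == 0.0 else 0.0
    return float(min(1.0, 2.0 * stats.norm.sf(abs(pbs) / noise_sd)))


def _random_oligo(rng: np.random.Generator, length: int, offset: int) -> tuple[str, str, str, str]:
    bases = "ACGT"
    seq = "".join(rng.choice(list(bases), size=length))
    ref = seq[offset - 1]
    alt = rng.choice([b for b in bases if b != ref])
    alt_seq = seq[: offset - 1] + alt + seq[offset:]
    return seq, alt_seq, ref, alt


def simulate_pair(
    params: SimulationParams,
    pair_index: int,
    rng: np.random.Generator,
) -> PairFixture:
    """Generate one allele pair driven by a latent preference effect.

    The effect is 0 with probability ``null_fraction``, otherwise
    +/- ``effect_magnitude`` with equal probability.  Each observable
    channel is coupling * delta plus Gaussian channel noise; PBS p-values
    come from the known null sd, so planted significance is exact by
    construction.  A true-effect pair gets a displaced binding blob in
    the alternative model with probability ``shift_prob``.
    """
    pair_id = f"pair{pair_index:05d}"
    if rng.random() < params.null_fraction:
        delta = 0.0
    else:
        delta = params.effect_magnitude * (1.0 if rng.random() < 0.5 else -1.0)

    ref_oligo, alt_oligo, ref, alt = _random_oligo(
        rng, params.duplex_len, params.variant_offset
    )
    x_iptm = params.c_iptm * delta + rng.normal(0.0, params.noise_sd_iptm)
    iptm_ref = float(np.clip(params.iptm_base + x_iptm / 2.0, 0.0, 1.0))
    iptm_alt = float(np.clip(params.iptm_base - x_iptm / 2.0, 0.0, 1.0))
    ddg_fwd = params.c_ddg * delta + rng.normal(0.0, params.noise_sd_ddg)
    ddg_rev = -params.c_ddg * delta + rng.normal(0.0, params.noise_sd_ddg)
    x_int = params.c_interface * delta + rng.normal(0.0, params.noise_sd_interface)
    interface_ref = params.interface_base - x_int / 2.0
    interface_alt = params.interface_base + x_int / 2.0
    pbs = params.c_pbs * delta + rng.normal(0.0, params.noise_sd_pbs)

    shifted = bool(delta != 0.0 and rng.random() < params.shift_prob)
    center_ref = params.variant_offset
    center_alt = center_ref
    if shifted:
        half = params.site_width // 2
        if center_ref + params.shift_bp + half <= params.duplex_len:
            center_alt = center_ref + params.shift_bp
        else:
            center_alt = center_ref - params.shift_bp

    model_ref = model_alt = None
    if params.write_structures:
        model_ref = place_tf_blob(
            build_bdna_duplex(ref_oligo), center_ref, params.site_width,
            model_id=f"{pair_id}_ref",
        )
        model_alt = place_tf_blob(
            build_bdna_duplex(alt_oligo), center_alt, params.site_width,
            model_id=f"{pair_id}_alt",
        )

    pair = AllelePair(
        pair_id=pair_id,
        tf="TFSIM",
        chrom="chrS",
        pos=1_000_000 + pair_index,
        ref_allele=ref,
        alt_allele=alt,
        ref_oligo=ref_oligo,
        alt_oligo=alt_oligo,
        variant_offset=params.variant_offset,
        pbs=float(pbs),
        pbs_p=_pbs_pvalue(float(pbs), params.noise_sd_pbs),
    )
    return PairFixture(
        pair=pair,
        conf_ref=ConfidenceSummary(f"{pair_id}_ref", iptm_ref),
        conf_alt=ConfidenceSummary(f"{pair_id}_alt", iptm_alt),
        energies=EnergyRecord(
            pair_id=pair_id,
            ddg_fwd=float(ddg_fwd),
            ddg_rev=float(ddg_rev),
            interface_ref=float(interface_ref),
            interface_alt=float(interface_alt),
        ),
        model_ref=model_ref,
        model_alt=model_alt,
        delta=delta,
        shifted=shifted,
        site_center_ref=center_ref,
        site_center_alt=center_alt,
    )


def simulate_cohort(
    params: SimulationParams,
    out_dir: str | Path,
    overwrite: bool = False,
) -> Path:
    """Write a complete fixture cohort and its manifest.

    Layout: ``models/`` (PDB pairs, unless structures are disabled),
    ``confidence/`` (one JSON per model), ``fxout/`` (Dif forward/reverse
    and Interaction ref/alt per pair), ``pbs_table.tsv``, ``manifest.tsv``
    (latent truths) and ``manifest.json`` (parameters and seed).
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"{out} exists and is not empty (use overwrite)")
    (out / "models").mkdir(parents=True, exist_ok=True)
    (out / "confidence").mkdir(exist_ok=True)
    (out / "fxout").mkdir(exist_ok=True)

    rng = np.random.default_rng(params.seed)
    pairs, manifest_rows = [], []
    for i in range(params.n_pairs):
        fx = simulate_pair(params, i, rng)
        pid = fx.pair.pair_id
        if fx.model_ref is not None:
            write_structure_pdb(fx.model_ref, out / "models" / f"{pid}_ref.pdb")
            write_structure_pdb(fx.model_alt, out / "models" / f"{pid}_alt.pdb")
        for tag, conf in (("ref", fx.conf_ref), ("alt", fx.conf_alt)):
            (out / "confidence" / f"{pid}_{tag}.json").write_text(
                json.dumps({"iptm": round(conf.iptm, 6)}) + "\n"
            )
        write_dif_fxout(
            out / "fxout" / f"Dif_{pid}_fwd.fxout", f"{pid}_ref", [fx.energies.ddg_fwd]
        )
        write_dif_fxout(
            out / "fxout" / f"Dif_{pid}_rev.fxout", f"{pid}_alt", [fx.energies.ddg_rev]
        )
        for tag, e in (("ref", fx.energies.interface_ref),
                       ("alt", fx.energies.interface_alt)):
            write_interaction_fxout(
                out / "fxout" / f"Interaction_{pid}_{tag}.fxout",
                f"{pid}_{tag}",
                [("A", "B", e / 2.0), ("A", "C", e / 2.0)],
            )
        pairs.append(fx.pair)
        manifest_rows.append(
            {
                "pair_id": pid,
                "delta": fx.delta,
                "shifted": int(fx.shifted),
                "site_center_ref": fx.site_center_ref,
                "site_center_alt": fx.site_center_alt,
            }
        )

    write_pbs_table(pairs, out / "pbs_table.tsv")
    import pandas as pd

    pd.DataFrame(manifest_rows).to_csv(out / "manifest.tsv", sep="\t", index=False)
    (out / "manifest.json").write_text(
        json.dumps({"params": asdict(params)}, indent=2) + "\n"
    )
    return out
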