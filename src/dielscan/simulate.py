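"""Synthetic promoter alignments with planted, recoverable structure.

The generator evolves sequences site by site along a user-supplied tree
under HKY with discrete-gamma rate variation, but with a position-dependent
equilibrium composition: at alignment position ``x`` the stationary
frequencies are ``pi_G = pi_C = g(x)/2`` and ``pi_A = pi_T = (1-g(x))/2``,
where ``g`` is a piecewise-linear GC profile (default: a ramp from 55 %
distal to 62 % proximal, peaking near the third planted E-box).  This
emulates the proximal GC rise of real promoter regions.

Trait-linked "core" intervals depress the target GC by ``delta_gc`` for the
maximal subtrees whose tips all carry the affected trait.  The shift is
applied as a compositional jump at the stem of each affected subtree (core
sites are redrawn from the shifted equilibrium there) followed by ordinary
evolution under the shifted equilibrium inside the subtree — emulating
convergent compositional shifts old enough to be near their new equilibrium,
which is the regime the scan is designed to detect.

E-box hexamers are overwritten post hoc at fixed positions (with optional
per-tip substitutions), and deletions are applied as '-' runs; both are
recorded in a machine-readable truth object alongside the true tree.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from dielscan.gcscan import gc_content
from dielscan.io import Alignment, SampleMetadata, SampleRow, SequenceRecord
from dielscan.phylo import Node, Tree, _HKYModel, discrete_gamma_rates

_BASES = "ACGT"


@dataclass(frozen=True)
class CoreSpec:
    """A trait-linked GC-depressed interval (0-based half-open columns)."""

    start: int
    end: int
    delta_gc: float
    affected_trait: str = "Nocturnal"


@dataclass(frozen=True)
class MotifSpec:
    """A planted motif: position, hexamer, and per-tip substitutions.

    ``substitutions`` is a tuple of (tip id, offset within motif, new base);
    the new base may be an IUPAC ambiguity code (e.g. 'S' for a heterozygous
    G/C call).
    """

    position: int
    hexamer: str = "CACGTG"
    substitutions: tuple[tuple[str, int, str], ...] = ()


@dataclass(frozen=True)
class DeletionSpec:
    """A fixed deletion: these tips get '-' over [start, end)."""

    tips: tuple[str, ...]
    start: int
    end: int


@dataclass(frozen=True)
class SimulationConfig:
    tree_newick: str
    tip_traits: dict[str, str]  # tip id -> behavior (Diurnal/Nocturnal)
    length: int
    seed: int
    tip_groups: dict[str, str] = field(default_factory=dict)
    tip_species: dict[str, str] = field(default_factory=dict)
    kappa: float = 4.0
    alpha: float = 1.9765
    n_categories: int = 4
    gc_profile: tuple[tuple[float, float], ...] = ((0.0, 0.55), (0.85, 0.62), (1.0, 0.60))
    cores: tuple[CoreSpec, ...] = ()
    motifs: tuple[MotifSpec, ...] = ()
    deletions: tuple[DeletionSpec, ...] = ()
    small_indel_rate: float = 0.0  # expected random deletions per site per tip

    def gc_at(self, positions: np.ndarray) -> np.ndarray:
        """Target GC fraction g(x) at each 0-based position."""
        xs = np.array([p for p, _ in self.gc_profile])
        ys = np.array([g for _, g in self.gc_profile])
        frac = positions / max(self.length - 1, 1)
        return np.interp(frac, xs, ys)


@dataclass
class SimTruth:
    """Machine-readable ground truth matching the emitted alignment."""

    tree_newick: str
    cores: list[dict]
    motifs: list[dict]
    deletions: list[dict]
    seed: int

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def _pi_from_gc(g: float) -> np.ndarray:
    g = min(max(g, 0.02), 0.98)
    return np.array([(1 - g) / 2, g / 2, g / 2, (1 - g) / 2])


class _ModelCache:
    """HKY models and transition matrices per (gc bin, scaled branch length)."""

    def __init__(self, kappa: float):
        self.kappa = kappa
        self._models: dict[float, _HKYModel] = {}
        self._pmats: dict[tuple[float, float], np.ndarray] = {}

    def model(self, g_bin: float) -> _HKYModel:
        if g_bin not in self._models:
            self._models[g_bin] = _HKYModel(self.kappa, _pi_from_gc(g_bin))
        return self._models[g_bin]

    def pmat(self, g_bin: float, t: float) -> np.ndarray:
        key = (g_bin, round(t, 10))
        if key not in self._pmats:
            self._pmats[key] = self.model(g_bin).transition_matrix(t)
        return self._pmats[key]


def _sample_rows(probs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One categorical draw per row of a (n, 4) probability matrix."""
    u = rng.random(probs.shape[0])
    return (probs.cumsum(axis=1) > u[:, None]).argmax(axis=1)


def _affected_subtree_nodes(tree: Tree, affected_tips: set[str]) -> tuple[set[int], set[int]]:
    """Nodes inside maximal all-affected subtrees, and the subtree stem nodes."""
    tipsets = tree._tipsets()
    inside: set[int] = set()
    stems: set[int] = set()
    for n in tree.postorder():
        if n.parent is None:
            continue
        mine = tipsets[id(n)] <= affected_tips
        if not mine:
            continue
        parent_all = n.parent.parent is not None and tipsets[id(n.parent)] <= affected_tips
        if not parent_all:
            stems.add(id(n))
        inside.add(id(n))
    return inside, stems


def simulate_alignment(config: SimulationConfig) -> tuple[Alignment, SampleMetadata, SimTruth]:
    """Simulate an alignment, its metadata and the planted ground truth.

    The same config and seed always produce byte-identical output.
    """
    tree = Tree.from_newick(config.tree_newick)
    tip_names = tree.tip_names()
    if set(tip_names) != set(config.tip_traits):
        raise ValueError(
            f"trait map does not match tree tips: tree={sorted(tip_names)}, "
            f"traits={sorted(config.tip_traits)}"
        )
    rng = np.random.default_rng(config.seed)
    L = config.length
    positions = np.arange(L)
    g_base = config.gc_at(positions)
    rates = discrete_gamma_rates(config.alpha, config.n_categories)
    site_cat = rng.integers(0, config.n_categories, size=L)
    cache = _ModelCache(config.kappa)

    # per-core membership of nodes (inside subtree / stem edges) and site masks
    core_site_delta = np.zeros(L)
    core_masks = []
    for core in config.cores:
        mask = (positions >= core.start) & (positions < core.end)
        affected = {t for t in tip_names if config.tip_traits[t] == core.affected_trait}
        inside, stems = _affected_subtree_nodes(tree, affected)
        core_masks.append((mask, core.delta_gc, inside, stems))

    def g_bin(values: np.ndarray) -> np.ndarray:
        return np.round(values * 400) / 400  # 0.0025 GC granularity for caching

    # root states from the baseline stationary composition
    states = {}
    root_states = np.empty(L, dtype=np.int64)
    gb = g_bin(g_base)
    for b in np.unique(gb):
        idx = np.flatnonzero(gb == b)
        pi = _pi_from_gc(float(b))
        root_states[idx] = _sample_rows(np.tile(pi, (len(idx), 1)), rng)
    states[id(tree.root)] = root_states

    # preorder branch sampling
    order = [n for n in reversed(tree.postorder())]
    for node in order:
        if node.parent is None:
            continue
        t = float(node.length or 0.0)
        parent_states = states[id(node.parent)]
        child_states = parent_states.copy()
        # per-site effective target GC and regime on this branch
        g_eff = g_base.copy()
        jump_mask = np.zeros(L, dtype=bool)
        for mask, delta, inside, stems in core_masks:
            if id(node) in inside:
                g_eff = np.where(mask, g_base - delta, g_eff)
                if id(node) in stems:
                    jump_mask |= mask
        gb_eff = g_bin(g_eff)
        # stem edges of affected subtrees: redraw core sites from the shifted
        # equilibrium (compositional jump), other sites evolve normally
        for b in np.unique(gb_eff[jump_mask]):
            idx = np.flatnonzero(jump_mask & (gb_eff == b))
            pi = _pi_from_gc(float(b))
            child_states[idx] = _sample_rows(np.tile(pi, (len(idx), 1)), rng)
        evolve = ~jump_mask
        key = gb_eff + site_cat * 10  # g in [0,1], so this is unique per (g_bin, category)
        for k in np.unique(key[evolve]):
            idx = np.flatnonzero(evolve & (key == k))
            b = float(gb_eff[idx[0]])
            c = int(site_cat[idx[0]])
            P = cache.pmat(b, t * float(rates[c]))
            child_states[idx] = _sample_rows(P[parent_states[idx]], rng)
        states[id(node)] = child_states

    base_arr = np.array(list(_BASES))
    rows = {n.name: base_arr[states[id(n)]].copy() for n in tree.tips()}

    # plant motifs (overwrite, then per-tip substitutions)
    for m in config.motifs:
        if m.position + len(m.hexamer) > L:
            raise ValueError(f"motif at {m.position} exceeds alignment length {L}")
        for name in rows:
            rows[name][m.position : m.position + len(m.hexamer)] = list(m.hexamer)
        for tip, offset, base in m.substitutions:
            rows[tip][m.position + offset] = base

    # fixed deletions
    for d in config.deletions:
        for tip in d.tips:
            rows[tip][d.start : d.end] = "-"

    # optional scattered small deletions (1-10 bp), avoiding motif columns
    if config.small_indel_rate > 0:
        protected = np.zeros(L, dtype=bool)
        for m in config.motifs:
            protected[m.position : m.position + len(m.hexamer)] = True
        for name in sorted(rows):
            n_del = rng.poisson(config.small_indel_rate * L)
            for _ in range(n_del):
                size = int(rng.integers(1, 11))
                start = int(rng.integers(0, max(L - size, 1)))
                if protected[start : start + size].any():
                    continue
                rows[name][start : start + size] = "-"

    records = tuple(SequenceRecord(name, "".join(rows[name])) for name in tip_names)
    alignment = Alignment(records)
    meta_rows = {
        name: SampleRow(
            species=config.tip_species.get(name, name),
            group=config.tip_groups.get(name, "Haplorhini"),
            behavior=config.tip_traits[name],
            in_primate_tests=(config.tip_groups.get(name, "Haplorhini") != "outgroup"),
        )
        for name in tip_names
    }
    metadata = SampleMetadata(meta_rows)
    truth = SimTruth(
        tree_newick=config.tree_newick,
        cores=[asdict(c) for c in config.cores],
        motifs=[asdict(m) for m in config.motifs],
        deletions=[asdict(d) for d in config.deletions],
        seed=config.seed,
    )
    return alignment, metadata, truth


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

#: Whole-sequence GC percentages of the study panel (one value per sequence),
#: used as the printed-data input to the group-summary path.
TABLE1_GC = {
    "Human": 58.5,
    "Per1Ai": 58.6,
    "Chimp": 58.6,
    "Gorilla": 58.1,
    "Orangutan": 58.9,
    "Gibbon": 58.8,
    "Macaque": 58.6,
    "Per1Marmoset": 57.3,
    "Per1Owl": 57.7,
    "Tarsier": 57.4,
    "Per1RL": 58.8,
    "Per1GG": 54.8,
    "Bushbaby": 54.9,
    "Per1LG": 55.5,
    "Mouse": 53.9,
}

_TABLE1_ROWS = [
    # id, species, group, behavior
    ("Human", "Homo sapiens", "Haplorhini", "Diurnal"),
    ("Per1Ai", "Pan troglodytes", "Haplorhini", "Diurnal"),
    ("Chimp", "Pan troglodytes", "Haplorhini", "Diurnal"),
    ("Gorilla", "Gorilla gorilla", "Haplorhini", "Diurnal"),
    ("Orangutan", "Pongo pygmaeus", "Haplorhini", "Diurnal"),
    ("Gibbon", "Nomascus leucogenys", "Haplorhini", "Diurnal"),
    ("Macaque", "Macaca mulatta", "Haplorhini", "Diurnal"),
    ("Per1Marmoset", "Callithrix jacchus", "Haplorhini", "Diurnal"),
    ("Per1Owl", "Aotus trivirgatus", "Haplorhini", "Nocturnal"),
    ("Tarsier", "Tarsius syrichta", "Haplorhini", "Nocturnal"),
    ("Per1RL", "Lemur catta", "Strepsirrhini", "Diurnal"),
    ("Per1GG", "Otolemur crassicaudatus", "Strepsirrhini", "Nocturnal"),
    ("Bushbaby", "Otolemur garnettii", "Strepsirrhini", "Nocturnal"),
    ("Per1LG", "Galago senegalensis", "Strepsirrhini", "Nocturnal"),
    ("Mouse", "Mus musculus", "outgroup", "Nocturnal"),
]

# Species-tree-shaped topology over the panel, with branch lengths plausible
# for a promoter region (substitutions/site).
_CATARRHINI = (
    "(((((Human:0.007,(Per1Ai:0.002,Chimp:0.002):0.005):0.002,Gorilla:0.009):0.008,"
    "Orangutan:0.017):0.003,Gibbon:0.020):0.006,Macaque:0.030)"
)
_NWM = "(Per1Marmoset:0.030,Per1Owl:0.030)"
_HAPLORHINI = "((" + _CATARRHINI + ":0.015," + _NWM + ":0.035):0.010,Tarsier:0.075)"
_STREPSIRRHINI = "(Per1RL:0.060,((Per1GG:0.010,Bushbaby:0.010):0.030,Per1LG:0.045):0.020)"
_PRIMATES = "(" + _HAPLORHINI + ":0.015," + _STREPSIRRHINI + ":0.040)"

TABLE1_TREE = "(" + _PRIMATES + ":0.08,Mouse:0.30);"
PRIMATE_TREE = _PRIMATES + ";"


def table1_fixture() -> tuple[SampleMetadata, str]:
    """The 15-sequence study panel: metadata plus a species-tree newick."""
    rows = {
        sid: SampleRow(species=sp, group=g, behavior=b, in_primate_tests=(g != "outgroup"))
        for sid, sp, g, b in _TABLE1_ROWS
    }
    return SampleMetadata(rows), TABLE1_TREE


def paper_like_config(
    seed: int,
    length: int = 4000,
    delta_gc: float = 0.08,
    include_outgroup: bool = False,
    small_indel_rate: float = 1e-4,
) -> SimulationConfig:
    """Study-shaped preset: 14 primates (15 with outgroup), ~4 kb, one
    nocturnal-linked GC-depressed core, three E-boxes (the third at the GC
    peak), a 130 bp deletion in the marmoset/owl monkey/tarsier, and a few
    scattered small deletions.

    The core sits at columns [1000, 1500); the first E-box is planted 223 bp
    downstream of the core's proximal edge, mirroring the geometry of the
    observed signal.
    """
    if length < 1000:
        raise ValueError("paper_like_config needs length >= 1000")
    metadata, _ = table1_fixture()
    tips = [sid for sid, *_ in _TABLE1_ROWS if include_outgroup or sid != "Mouse"]
    tree = TABLE1_TREE if include_outgroup else PRIMATE_TREE
    # feature positions scale with length; at the default 4 kb the core is
    # [1000, 1500), the deletion [1250, 1380) and E-box_1 sits at 1723
    core = CoreSpec(
        start=int(0.25 * length), end=int(0.375 * length), delta_gc=delta_gc,
        affected_trait="Nocturnal",
    )
    ebox1 = MotifSpec(
        position=core.end + 223,
        substitutions=(("Per1GG", 3, "S"),),  # heterozygous G/C at the fourth position
    )
    ebox2 = MotifSpec(
        position=int(0.65 * length),
        substitutions=(("Tarsier", 0, "T"), ("Per1Marmoset", 2, "A")),
    )
    ebox3 = MotifSpec(position=int(0.85 * length))
    deletion = DeletionSpec(
        tips=("Per1Marmoset", "Per1Owl", "Tarsier"),
        start=int(0.3125 * length),
        end=int(0.3125 * length) + 130,
    )
    return SimulationConfig(
        tree_newick=tree,
        tip_traits={t: metadata.rows[t].behavior for t in tips},
        tip_groups={t: metadata.rows[t].group for t in tips},
        tip_species={t: metadata.rows[t].species for t in tips},
        length=length,
        seed=seed,
        cores=(core,) if delta_gc != 0 else (),
        motifs=(ebox1, ebox2, ebox3),
        deletions=(deletion,),
        small_indel_rate=small_indel_rate,
    )


def star_null_config(seed: int, length: int = 4000) -> SimulationConfig:
    """Exchangeable null for calibration checks: the 14-taxon panel with no
    shared internal branches (star phylogeny, equal root-to-tip divergence)
    and no planted cores.

    Family-wise error control of the Bonferroni window scan is a statement
    about independent samples; this preset realises that sampling model.
    Under the species tree the same null is anti-conservative because the
    diel trait is confounded with clades (see the methods notes).
    """
    metadata, _ = table1_fixture()
    tips = [sid for sid, *_ in _TABLE1_ROWS if sid != "Mouse"]
    star = "(" + ",".join(f"{t}:0.12" for t in tips) + ");"
    return SimulationConfig(
        tree_newick=star,
        tip_traits={t: metadata.rows[t].behavior for t in tips},
        tip_groups={t: metadata.rows[t].group for t in tips},
        tip_species={t: metadata.rows[t].species for t in tips},
        length=length,
        seed=seed,
    )


SIX_TAXON_TREE = "((A:0.08,B:0.08):0.05,(C:0.08,D:0.08):0.05,(E:0.08,F:0.08):0.05);"


def six_taxon_config(seed: int, length: int = 5000) -> SimulationConfig:
    """Strong-signal preset for topology/bootstrap checks: six taxa in three
    well-separated cherries, flat base composition, no planted features."""
    return SimulationConfig(
        tree_newick=SIX_TAXON_TREE,
        tip_traits={t: ("Diurnal" if t in "ABC" else "Nocturnal") for t in "ABCDEF"},
        tip_groups={t: ("Haplorhini" if t in "ABC" else "Strepsirrhini") for t in "ABCDEF"},
        length=length,
        seed=seed,
        gc_profile=((0.0, 0.55), (1.0, 0.55)),
    )


def observed_gc_summary(alignment: Alignment) -> dict[str, float]:
    """Whole-row GC percent per sequence (convenience for presets/tests)."""
    return {r.id: gc_content(r.residues).percent for r in alignment.records}
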