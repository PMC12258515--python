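"""Synthetic TurboID experiments, selection screens and phosphosite tables
with known ground truth.

The generator emulates the statistical structure the analysis assumes:

* per-protein log2 baseline intensities drawn once from a normal;
* bait-specific additive log2 enrichment effects on designated interactor
  sets (independent sets per bait × EGF state; an allosteric-inhibitor state
  thins the interactor set, mimicking loss of interactions when the bait is
  locked in its auto-inhibited conformation);
* replicate noise;
* intensity-dependent (missing-not-at-random) dropout: a cell goes missing
  with probability logistic((midpoint − value)/slope), so low-intensity
  proteins — e.g. true interactors in the control group — can be completely
  absent from one group;
* degenerate-library selection-screen read counts generated under a
  ground-truth specificity matrix with softmax selection;
* phosphosite flanking windows, a designated subset planted as tight binders
  under the true matrix.

Every output is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .io import DEFAULT_VOCABULARY, AnnotationTable, IntensityTable
from .specificity import (
    AMINO_ACIDS,
    CENTER_CHAR,
    ScreenCounts,
    SpecificityMatrix,
    flank_positions,
)

#: the default bait panel: wild type plus ten disease-associated variants
DEFAULT_VARIANTS = (
    "WT",
    "T42A",
    "T52S",
    "E76K",
    "R138Q",
    "E139D",
    "Y279C",
    "T468M",
    "T507K",
    "Q510E",
    "Q510K",
)

_ETC_LABELS = (
    "complex_I_core",
    "complex_I_accessory",
    "complex_I_assembly",
    "complex_II",
    "complex_III",
    "complex_IV",
    "complex_V",
)

_SUBMITO = ("matrix", "intermembrane_space", "inner_membrane", "outer_membrane")
_SUBMITO_P = (0.4, 0.2, 0.2, 0.2)


@dataclass
class SimConfig:
    """Parameters of a synthetic TurboID experiment.

    Intensity parameters are in log2 units. ``interactor_bias`` maps a
    variant to ``(label, weight)``: when sampling that variant's interactors,
    proteins carrying the annotation label are picked with ``weight``-fold
    higher probability — used to plant compartment- or phospho-biased baits.
    """

    n_proteins: int = 3000
    variants: tuple[str, ...] = DEFAULT_VARIANTS
    control: str = "control"
    egf_states: tuple[str, ...] = ("-", "+")
    inhibitor_states: tuple[str, ...] = ("-",)
    n_replicates: int = 3
    baseline_mean: float = 25.0
    baseline_sd: float = 2.0
    interactor_fraction: float = 0.05
    effect_size_mean: float = 3.0
    effect_size_sd: float = 0.5
    noise_sd: float = 0.5
    dropout_midpoint: float | None = None  # default: baseline_mean − baseline_sd
    dropout_slope: float = 0.5
    dropout_enabled: bool = True
    inhibitor_retention: float = 0.3
    frac_phospho: float = 0.3
    frac_mitochondrial: float = 0.10
    frac_etc_given_mito: float = 0.35
    interactor_bias: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("baseline_sd", "effect_size_sd", "noise_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 < self.interactor_fraction < 1:
            raise ValueError("interactor_fraction must be in (0, 1)")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if self.control in self.variants:
            raise ValueError("control label must differ from every variant label")
        if self.dropout_slope < 0:
            raise ValueError("dropout_slope must be >= 0")

    @property
    def midpoint(self) -> float:
        if self.dropout_midpoint is None:
            return self.baseline_mean - self.baseline_sd
        return self.dropout_midpoint


@dataclass
class SyntheticTruth:
    """Ground truth against which recovery is scored.

    ``interactors[(variant, egf, inhibitor)]`` maps each true interactor to
    its log2 effect; proteins not listed have effect exactly 0.
    """

    interactors: dict[tuple[str, str, str], dict[str, float]]
    protein_labels: dict[str, set[str]]
    matrices: dict[str, SpecificityMatrix] = field(default_factory=dict)
    planted_sites: list[int] = field(default_factory=list)

    def true_effects(
        self, variant: str, egf: str = "-", inhibitor: str = "-"
    ) -> dict[str, float]:
        return dict(self.interactors.get((variant, egf, inhibitor), {}))

    def effect_of(
        self, protein_id: str, variant: str, egf: str = "-", inhibitor: str = "-"
    ) -> float:
        return self.interactors.get((variant, egf, inhibitor), {}).get(protein_id, 0.0)

    def to_annotations(self, vocabulary=DEFAULT_VOCABULARY) -> AnnotationTable:
        return AnnotationTable(
            {pid: labs for pid, labs in self.protein_labels.items() if labs},
            vocabulary,
        )

    def interactor_frame(self) -> pd.DataFrame:
        rows = [
            {
                "variant": variant,
                "egf": egf,
                "inhibitor": inh,
                "protein_id": pid,
                "effect": eff,
            }
            for (variant, egf, inh), effects in self.interactors.items()
            for pid, eff in effects.items()
        ]
        return pd.DataFrame(
            rows, columns=["variant", "egf", "inhibitor", "protein_id", "effect"]
        )


def _assign_labels(config: SimConfig, rng: np.random.Generator, ids: list[str]):
    labels: dict[str, set[str]] = {pid: set() for pid in ids}
    is_phospho = rng.random(len(ids)) < config.frac_phospho
    is_mito = rng.random(len(ids)) < config.frac_mitochondrial
    submito = rng.choice(len(_SUBMITO), size=len(ids), p=_SUBMITO_P)
    has_etc = rng.random(len(ids)) < config.frac_etc_given_mito
    etc = rng.choice(len(_ETC_LABELS), size=len(ids))
    for i, pid in enumerate(ids):
        if is_phospho[i]:
            labels[pid].add("has_pTyr_site")
        if is_mito[i]:
            labels[pid].add("mitochondrial")
            labels[pid].add(_SUBMITO[submito[i]])
            if has_etc[i]:
                labels[pid].add(_ETC_LABELS[etc[i]])
    return labels


def _pick_interactors(
    config: SimConfig,
    rng: np.random.Generator,
    ids: list[str],
    labels: dict[str, set[str]],
    variant: str,
) -> list[str]:
    n_pick = max(1, round(config.interactor_fraction * len(ids)))
    weights = np.ones(len(ids))
    if variant in config.interactor_bias:
        label, w = config.interactor_bias[variant]
        weights = np.array([w if label in labels[pid] else 1.0 for pid in ids])
    chosen = rng.choice(len(ids), size=n_pick, replace=False, p=weights / weights.sum())
    return [ids[i] for i in chosen]


def simulate_turboid(config: SimConfig) -> tuple[IntensityTable, SyntheticTruth]:
    """Generate a bait-panel TurboID intensity experiment with ground truth.

    Control samples carry no effects; each bait × EGF state gets an
    independent interactor set with log2 effects drawn from
    N(effect_size_mean, effect_size_sd²). MNAR dropout is applied cell-wise
    after noise.
    """
    rng = np.random.default_rng(config.seed)
    width = len(str(config.n_proteins))
    ids = [f"P{i:0{width}d}" for i in range(1, config.n_proteins + 1)]
    labels = _assign_labels(config, rng, ids)
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, config.n_proteins)

    interactors: dict[tuple[str, str, str], dict[str, float]] = {}
    for variant in config.variants:
        for egf in config.egf_states:
            base_set = _pick_interactors(config, rng, ids, labels, variant)
            effects = rng.normal(
                config.effect_size_mean, config.effect_size_sd, len(base_set)
            )
            base_effects = dict(zip(base_set, effects))
            for inh in config.inhibitor_states:
                if inh == "+":
                    keep = rng.random(len(base_set)) < config.inhibitor_retention
                    interactors[(variant, egf, inh)] = {
                        pid: eff
                        for (pid, eff), k in zip(base_effects.items(), keep)
                        if k
                    }
                else:
                    interactors[(variant, egf, inh)] = dict(base_effects)

    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    id_index = {pid: i for i, pid in enumerate(ids)}
    for variant in (*config.variants, config.control):
        for egf in config.egf_states:
            for inh in config.inhibitor_states:
                effect_vec = np.zeros(config.n_proteins)
                for pid, eff in interactors.get((variant, egf, inh), {}).items():
                    effect_vec[id_index[pid]] = eff
                for rep in range(1, config.n_replicates + 1):
                    name = f"{variant}.egf{egf}.inh{inh}.r{rep}"
                    values = (
                        baseline
                        + effect_vec
                        + rng.normal(0.0, config.noise_sd, config.n_proteins)
                    )
                    if config.dropout_enabled:
                        if config.dropout_slope == 0:
                            p_miss = (values < config.midpoint).astype(float)
                        else:
                            p_miss = expit(
                                (config.midpoint - values) / config.dropout_slope
                            )
                        drop = rng.random(config.n_proteins) < p_miss
                        values = np.where(drop, np.nan, values)
                    columns[name] = values
                    meta_rows.append(
                        {
                            "sample_id": name,
                            "variant": variant,
                            "egf": egf,
                            "inhibitor": inh,
                            "replicate": rep,
                        }
                    )
    values = pd.DataFrame(columns, index=pd.Index(ids, name="protein_id"))
    metadata = pd.DataFrame(meta_rows).set_index("sample_id")
    table = IntensityTable(values, metadata)
    truth = SyntheticTruth(interactors=interactors, protein_labels=labels)
    return table, truth


# ----------------------------------------------------------------------
# Specificity-screen simulation
# ----------------------------------------------------------------------


def make_true_matrix(
    half_width: int = 5,
    alphabet: str = AMINO_ACIDS,
    weight_sd: float = 1.0,
    domain: str = "SH2",
    seed: int = 0,
) -> SpecificityMatrix:
    """A random ground-truth specificity matrix, zero-centered per position."""
    rng = np.random.default_rng(seed)
    positions = flank_positions(half_width)
    w = rng.normal(0.0, weight_sd, size=(len(alphabet), len(positions)))
    w = w - w.mean(axis=0, keepdims=True)
    weights = pd.DataFrame(w, index=list(alphabet), columns=positions)
    return SpecificityMatrix(domain=domain, weights=weights, alphabet=alphabet)


def simulate_screen(
    true_matrix: SpecificityMatrix,
    n_library: int = 100_000,
    n_reads_input: int = 1_000_000,
    n_reads_selected: int = 1_000_000,
    selection_sharpness: float = 1.0,
    seed: int = 0,
    exclude_cys: bool = False,
) -> ScreenCounts:
    """Simulate a degenerate-library selection screen under a known matrix.

    Library peptides are uniform over the alphabet at each variable position
    (optionally excluding cysteine); input reads are multinomial over the
    library, selected reads multinomial with probability proportional to
    exp(selection_sharpness × true additive score).
    """
    if n_library < 100:
        raise ValueError("n_library must be >= 100 for matrix estimation")
    rng = np.random.default_rng(seed)
    draw_alphabet = true_matrix.alphabet
    if exclude_cys:
        draw_alphabet = draw_alphabet.replace("C", "")
    positions = true_matrix.positions
    n_pos = len(positions)
    letters = np.frombuffer(draw_alphabet.encode("ascii"), dtype=np.uint8)
    pep = rng.integers(0, len(draw_alphabet), size=(n_library, n_pos))

    # per-position weight lookup in draw-alphabet order
    w = np.stack(
        [true_matrix.weights.loc[list(draw_alphabet), p].to_numpy() for p in positions],
        axis=1,
    )  # |draw_alphabet| × n_pos
    scores = w[pep, np.arange(n_pos)].sum(axis=1)

    input_counts = rng.multinomial(n_reads_input, np.full(n_library, 1.0 / n_library))
    logits = selection_sharpness * scores
    p_sel = np.exp(logits - logits.max())
    p_sel /= p_sel.sum()
    selected_counts = rng.multinomial(n_reads_selected, p_sel)

    h = true_matrix.half_width
    chars = letters[pep]
    seqs = [
        bytes(row[:h]).decode() + CENTER_CHAR + bytes(row[h:]).decode()
        for row in chars
    ]
    table = pd.DataFrame(
        {
            "sequence": seqs,
            "input_count": input_counts,
            "selected_count": selected_counts,
        }
    )
    return ScreenCounts(table, alphabet=true_matrix.alphabet)


def simulate_phosphosites(
    n_sites: int,
    window: int,
    truth: SyntheticTruth,
    seed: int = 0,
    planted_fraction: float = 0.02,
) -> tuple[pd.DataFrame, AnnotationTable]:
    """Random phosphosite flanking windows on the experiment's proteins.

    A ``planted_fraction`` subset of sites is sampled position-wise with
    probability proportional to 2^weight under the ground-truth matrices in
    ``truth`` (alternating domains) — planted tight binders. The returned
    annotation table marks every protein carrying at least one site as a
    phosphoprotein; planted row indices are recorded in
    ``truth.planted_sites``.
    """
    rng = np.random.default_rng(seed)
    ids = sorted(truth.protein_labels)
    if not ids:
        raise ValueError("truth carries no proteins")
    matrices = list(truth.matrices.values())
    if matrices:
        for m in matrices:
            if m.half_width != window:
                raise ValueError(
                    f"window half-width {window} does not match matrix positions "
                    f"±{m.half_width}"
                )
    truth.planted_sites = []
    if n_sites == 0:
        empty = pd.DataFrame(columns=["protein_id", "position", "window"])
        return empty, AnnotationTable({})

    n_planted = round(planted_fraction * n_sites) if matrices else 0
    alphabet = matrices[0].alphabet if matrices else AMINO_ACIDS
    n_pos = 2 * window

    def random_windows(n: int) -> list[str]:
        idx = rng.integers(0, len(alphabet), size=(n, n_pos))
        return [
            "".join(alphabet[j] for j in row[:window])
            + CENTER_CHAR
            + "".join(alphabet[j] for j in row[window:])
            for row in idx
        ]

    def planted_windows(n: int) -> list[str]:
        out = []
        for i in range(n):
            m = matrices[i % len(matrices)]
            chars = []
            for pos in m.positions:
                w = m.weights[pos].to_numpy()
                p = np.power(2.0, w)
                p /= p.sum()
                chars.append(rng.choice(list(m.alphabet), p=p))
            out.append("".join(chars[:window]) + CENTER_CHAR + "".join(chars[window:]))
        return out

    windows = random_windows(n_sites - n_planted) + planted_windows(n_planted)
    truth.planted_sites = list(range(n_sites - n_planted, n_sites))
    proteins = [ids[i] for i in rng.integers(0, len(ids), size=n_sites)]
    positions = rng.integers(window + 1, 1000, size=n_sites)
    sites = pd.DataFrame(
        {"protein_id": proteins, "position": positions, "window": windows}
    )
    annotations = AnnotationTable(
        {pid: {"has_pTyr_site"} for pid in set(proteins)}
    )
    return sites, annotations
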