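"""Seeded generators for CLIP-like tag sets, matched controls and FP titrations.

Every generator is a pure function of its spec (including the seed): the same
spec yields bit-identical output.  Randomness uses a single global seed with
per-tag derived substreams (`numpy.random.SeedSequence.spawn`), so results do
not depend on generation order.

The tag generator emulates the study conditions of an in vivo CLIP experiment
on mouse testis: short tags (~40 nt), an A/U-rich genomic base composition,
and - in a controllable fraction of tags - an embedded pair of (A/U)AA-bearing
motifs at a controllable intervening spacing, mimicking bipartite
protein-dimer binding sites.  Embedding overwrites background residues rather
than inserting, so generated lengths are exact and control sets can be
length-matched, as a matched genomic control requires.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from starbind.sequences import NucleotideSequence, TagSet

logger = logging.getLogger(__name__)

RNA_BASES = ("A", "C", "G", "U")

#: Mouse-genome-like background composition (A, C, G, U).
MOUSE_LIKE_FREQUENCIES = (0.29, 0.21, 0.21, 0.29)

__all__ = [
    "MOUSE_LIKE_FREQUENCIES",
    "EmbeddedPair",
    "TagGeneratorSpec",
    "TitrationSpec",
    "generate_tags",
    "generate_control",
    "generate_fp_titration",
]


def _default_spacings() -> tuple[int, ...]:
    return tuple(range(20, 31))


@dataclass(frozen=True)
class TagGeneratorSpec:
    """Parameters for the CLIP-like tag generator.

    ``spacing_choices`` is the support of a uniform discrete distribution of
    intervening nucleotides between the two embedded motif copies (default
    uniform on 20..30 nt, the separation window where bipartite sites are
    enriched in vivo).
    """

    n_tags: int = 2000
    length_mean: float = 40.0
    length_sd: float = 4.0
    base_frequencies: tuple[float, float, float, float] = MOUSE_LIKE_FREQUENCIES
    embed_fraction: float = 0.0
    embed_motif: str = "UAAA"
    spacing_choices: tuple[int, ...] = field(default_factory=_default_spacings)
    seed: int = 0
    #: if True, a sampled tag too short for its motif pair is an error naming
    #: the tag index; by default the tag is lengthened to exactly the pair span.
    strict_length: bool = False

    def validate(self) -> None:
        if self.n_tags < 0:
            raise ValueError("n_tags must be >= 0")
        if abs(sum(self.base_frequencies) - 1.0) > 1e-9:
            raise ValueError("base_frequencies must sum to 1 within 1e-9")
        if any(f < 0 for f in self.base_frequencies):
            raise ValueError("base_frequencies must be non-negative")
        if not 0.0 <= self.embed_fraction <= 1.0:
            raise ValueError("embed_fraction must lie in [0, 1]")
        if self.embed_fraction > 0:
            if not self.embed_motif:
                raise ValueError("embed_motif must be non-empty when embedding")
            if any(b not in RNA_BASES for b in self.embed_motif):
                raise ValueError("embed_motif must be over {A,C,G,U}")
            if not self.spacing_choices or any(s < 0 for s in self.spacing_choices):
                raise ValueError("spacing_choices must be non-negative and non-empty")


@dataclass(frozen=True)
class TitrationSpec:
    """Parameters for a simulated fluorescence-polarization titration.

    Defaults mirror a plate assay: protein serially two-fold diluted from
    200 uM down (15 points) plus a protein-free well, labelled RNA at 0.2 uM.
    Signals are polarization in arbitrary units.
    """

    true_kd: float = 5.0
    f_free: float = 50.0
    f_bound: float = 250.0
    rna_total: float = 0.2
    concentrations: tuple[float, ...] = ()
    noise_sd: float = 0.0
    model: str = "quadratic"
    seed: int = 0

    def resolved_concentrations(self) -> np.ndarray:
        if self.concentrations:
            conc = np.asarray(self.concentrations, dtype=float)
        else:
            conc = np.concatenate([[0.0], 200.0 / 2.0 ** np.arange(14, -1, -1.0)])
        return np.sort(conc)

    def validate(self) -> None:
        if self.true_kd <= 0:
            raise ValueError("true_kd must be > 0")
        if self.f_bound == self.f_free:
            raise ValueError("f_bound must differ from f_free")
        if self.rna_total <= 0:
            raise ValueError("rna_total must be > 0")
        conc = self.resolved_concentrations()
        if (conc < 0).any():
            raise ValueError("concentrations must be non-negative")
        if 0.0 not in conc:
            raise ValueError("concentrations must include 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _random_residues(rng: np.random.Generator, length: int, frequencies) -> np.ndarray:
    return rng.choice(np.array(RNA_BASES), size=length, p=np.asarray(frequencies))


@dataclass(frozen=True)
class EmbeddedPair:
    """Ground truth for one embedded motif pair: tag index, offset, spacing."""

    tag_index: int
    offset: int
    spacing: int


def generate_tags(spec: TagGeneratorSpec, return_truth: bool = False):
    """Generate a CLIP-like tag set with optional embedded motif pairs.

    Background residues are i.i.d. draws from ``spec.base_frequencies``.  For
    ``embed_fraction`` of the tags (chosen at random), two copies of
    ``embed_motif`` overwrite the background at a sampled intervening spacing;
    the pair is placed at a random offset that keeps it fully inside the tag.

    With ``return_truth`` the sampled embedding positions and spacings are
    returned alongside the tags as a list of :class:`EmbeddedPair`, for
    validating downstream analyses against known ground truth.

    Raises
    ------
    ValueError
        If ``strict_length`` is set and a generated tag is too short to hold
        the requested motif pair (the tag index is named).
    """
    spec.validate()
    root = np.random.SeedSequence(spec.seed)
    master = np.random.default_rng(root)
    n = spec.n_tags
    lengths = np.maximum(
        1, np.rint(master.normal(spec.length_mean, spec.length_sd, size=n)).astype(int)
    )
    embed_mask = master.random(n) < spec.embed_fraction
    streams = root.spawn(n)

    tags = TagSet(name=f"synthetic_clip_seed{spec.seed}")
    motif = spec.embed_motif
    truth: list[EmbeddedPair] = []
    n_lengthened = 0
    for i in range(n):
        rng = np.random.default_rng(streams[i])
        length = int(lengths[i])
        spacing = None
        if embed_mask[i]:
            spacing = int(rng.choice(np.asarray(spec.spacing_choices)))
            span = 2 * len(motif) + spacing
            if span > length:
                if spec.strict_length:
                    raise ValueError(
                        f"tag {i}: length {length} cannot hold motif pair of span {span}"
                    )
                length = span
                n_lengthened += 1
        residues = _random_residues(rng, length, spec.base_frequencies)
        if spacing is not None:
            span = 2 * len(motif) + spacing
            offset = int(rng.integers(0, length - span + 1))
            residues[offset : offset + len(motif)] = list(motif)
            down = offset + len(motif) + spacing
            residues[down : down + len(motif)] = list(motif)
            truth.append(EmbeddedPair(tag_index=i, offset=offset, spacing=spacing))
        tags.sequences.append(NucleotideSequence(f"tag{i}", "".join(residues)))
    if n_lengthened:
        logger.info(
            "lengthened %d of %d tags to hold their embedded motif pair", n_lengthened, n
        )
    if return_truth:
        return tags, truth
    return tags


def generate_control(
    lengths: Sequence[int],
    base_frequencies: Sequence[float] = MOUSE_LIKE_FREQUENCIES,
    seed: int = 0,
) -> TagSet:
    """Generate a background set: one i.i.d. random sequence per requested length.

    Emulates randomly selected genomic sequence, length-matched to a tag set
    (pass ``[len(t) for t in tags]``).
    """
    if len(lengths) == 0:
        raise ValueError("lengths must be non-empty")
    if any(l < 0 for l in lengths):
        raise ValueError("lengths must be non-negative")
    if abs(sum(base_frequencies) - 1.0) > 1e-9:
        raise ValueError("base_frequencies must sum to 1 within 1e-9")
    root = np.random.SeedSequence(seed)
    streams = root.spawn(len(lengths))
    control = TagSet(name=f"synthetic_control_seed{seed}")
    for i, length in enumerate(lengths):
        rng = np.random.default_rng(streams[i])
        control.sequences.append(
            NucleotideSequence(f"ctrl{i}", "".join(_random_residues(rng, length, base_frequencies)))
        )
    return control


def generate_fp_titration(spec: TitrationSpec):
    """Simulate an FP titration: binding-model prediction plus Gaussian noise.

    Returns a :class:`starbind.fp.Titration` whose signals are
    ``predict_signal(...) + N(0, noise_sd)``, deterministic for a fixed seed.
    """
    from starbind.fp import Titration, predict_signal

    spec.validate()
    conc = spec.resolved_concentrations()
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    signal = predict_signal(
        spec.true_kd, spec.f_free, spec.f_bound, spec.rna_total, conc, model=spec.model
    )
    if spec.noise_sd > 0:
        signal = signal + rng.normal(0.0, spec.noise_sd, size=conc.size)
    return Titration(
        concentrations=conc, signals=np.asarray(signal, dtype=float), rna_total=spec.rna_total
    )
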