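"""Ground-truthed synthetic small-RNA libraries.

The generator emulates the statistical structure of deep-sequenced
small-RNA libraries from a species without a reference genome:

* planted hairpin precursors (60-100 nt) with a mature arm and the star
  arm pairing it, belonging to known families or to novel (conserved /
  specific) loci;
* extremely skewed locus abundances (discrete power law);
* 5'/3' end heterogeneity from imprecise processing, plus untemplated
  3' additions favouring U then A;
* a 36-nt artefact class with U-rich low-complexity 3' tails, almost all
  singleton reads;
* structural/foreign contamination (rRNA, tRNA, snRNA, piRNA/transposon,
  endosymbiont fragments);
* two library profiles — "whole_body" (known-miRNA enriched) and "ovary"
  (novel-candidate enriched) — calibrated so the 21-23-nt read fraction
  lands near the empirically observed 72% / 63%.

Every emitted unique read is recorded in a truth manifest with its origin
and exact per-library counts, so each pipeline stage can be scored
against the planted truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .precursor import Contig, ContigHit, call_duplex, find_duplexes, fold_hairpin
from .records import ReadRecord, ReferenceSet, revcomp

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class LibraryProfile:
    known_multiplier: float
    novel_multiplier: float
    artefact_fraction: float
    contaminant_fraction: float


@dataclass
class PlantedHairpin:
    id: str
    sequence: str
    mature: tuple[int, int]
    star: tuple[int, int]
    family_tag: str  # known:<name> | novel_conserved | novel_specific

    @property
    def mature_seq(self) -> str:
        return self.sequence[self.mature[0] : self.mature[1]]

    @property
    def star_seq(self) -> str:
        return self.sequence[self.star[0] : self.star[1]]

    @property
    def is_known(self) -> bool:
        return self.family_tag.startswith("known:")


@dataclass
class SimulationConfig:
    """Defaults define the simulated study conditions; see docs/methods.md."""

    n_known: int = 20
    n_novel_conserved: int = 15
    n_novel_specific: int = 25
    mature_length_probs: dict[int, float] = field(
        default_factory=lambda: {21: 0.2, 22: 0.6, 23: 0.2}
    )
    loop_range: tuple[int, int] = (8, 15)
    pad_range: tuple[int, int] = (4, 10)
    min_precursor_len: int = 60
    # locus expression: discrete power law (read counts per mature arm)
    abundance_exponent: float = 1.5
    locus_min_count: int = 500
    locus_max_count: int = 50_000
    star_ratio_range: tuple[float, float] = (0.25, 0.9)
    # end heterogeneity
    shift_probs: dict[int, float] = field(
        default_factory=lambda: {-2: 0.02, -1: 0.09, 0: 0.78, 1: 0.09, 2: 0.02}
    )
    tail_add_prob: float = 0.20
    tail_base_probs: dict[str, float] = field(
        default_factory=lambda: {"T": 0.6, "A": 0.3, "G": 0.05, "C": 0.05}
    )
    # artefact class
    artefact_length: int = 36
    artefact_tail_t_prob: float = 0.6
    # contaminant fragments
    contaminant_count_exponent: float = 2.0
    contaminant_max_count: int = 1000
    library_profiles: dict[str, LibraryProfile] = field(
        default_factory=lambda: {
            "whole_body": LibraryProfile(2.0, 0.085, 0.13, 0.005),
            "ovary": LibraryProfile(0.085, 2.0, 0.22, 0.005),
        }
    )
    library_jitter_sigma: float = 0.3
    # qPCR
    qpcr_replicates: int = 3
    qpcr_noise_sd: float = 0.15
    qpcr_baseline_ct: float = 34.0
    qpcr_efficiency: float = 2.0

    def __post_init__(self) -> None:
        for probs in (self.mature_length_probs, self.shift_probs, self.tail_base_probs):
            vals = np.array(list(probs.values()))
            if np.any(vals < 0) or not np.isclose(vals.sum(), 1.0):
                raise ValueError(f"probabilities must be in [0,1] and sum to 1: {probs}")
        if not 0 <= self.tail_add_prob <= 1:
            raise ValueError("tail_add_prob outside [0,1]")
        for name, prof in self.library_profiles.items():
            if prof.artefact_fraction + prof.contaminant_fraction >= 1:
                raise ValueError(f"profile {name!r}: fractions must sum to < 1")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _power_law_counts(
    rng: np.random.Generator, exponent: float, kmin: int, kmax: int, size: int
) -> np.ndarray:
    """Discrete truncated power law P(k) ~ k^-exponent via inverse CDF."""
    u = rng.random(size)
    a = 1.0 - exponent
    x = (kmin**a + u * (kmax**a - kmin**a)) ** (1.0 / a)
    return np.clip(np.round(x).astype(np.int64), kmin, kmax)


def generate_hairpin_set(config: SimulationConfig, seed: int) -> list[PlantedHairpin]:
    """Deterministically generate planted hairpins that pass their own fold check.

    Each precursor is a perfect inverted repeat (stem = mature arm and its
    reverse complement) around a loop, with random pads; a candidate draw is
    kept only if fold_hairpin recovers both arms at pairedness >= 0.8 and
    the planted mature/star intervals form a duplex on opposite arms.
    """
    rng = np.random.default_rng(seed)
    tags = (
        [f"known:fam{i + 1}" for i in range(config.n_known)]
        + ["novel_conserved"] * config.n_novel_conserved
        + ["novel_specific"] * config.n_novel_specific
    )
    lengths = np.array(list(config.mature_length_probs))
    lprobs = np.array(list(config.mature_length_probs.values()))
    hairpins: list[PlantedHairpin] = []
    seen_matures: set[str] = set()
    for idx, tag in enumerate(tags):
        hid = f"hp{idx + 1:03d}"
        for _attempt in range(200):
            mlen = int(rng.choice(lengths, p=lprobs))
            loop_len = int(rng.integers(config.loop_range[0], config.loop_range[1] + 1))
            pad5 = int(rng.integers(config.pad_range[0], config.pad_range[1] + 1))
            pad3 = int(rng.integers(config.pad_range[0], config.pad_range[1] + 1))
            arm5 = _random_seq(rng, mlen)
            seq = (
                _random_seq(rng, pad5)
                + arm5
                + _random_seq(rng, loop_len)
                + revcomp(arm5)
                + _random_seq(rng, pad3)
            )
            if len(seq) < config.min_precursor_len:
                seq += _random_seq(rng, config.min_precursor_len - len(seq))
            iv5 = (pad5, pad5 + mlen)
            iv3 = (pad5 + mlen + loop_len, pad5 + 2 * mlen + loop_len)
            mature, star = (iv5, iv3) if idx % 2 == 0 else (iv3, iv5)
            hp = PlantedHairpin(hid, seq, mature, star, tag)
            if hp.mature_seq in seen_matures:
                continue
            if _hairpin_self_check(hp):
                seen_matures.add(hp.mature_seq)
                hairpins.append(hp)
                break
        else:
            raise RuntimeError(f"could not generate a foldable hairpin for {hid}")
    return hairpins


def _hairpin_self_check(hp: PlantedHairpin) -> bool:
    fold = fold_hairpin(hp.sequence)
    if fold.arm5 is None or fold.pairedness5 < 0.8 or fold.pairedness3 < 0.8:
        return False
    hits = [
        ContigHit("mature", hp.id, hp.mature[0], hp.mature[1], "+", 1.0),
        ContigHit("star", hp.id, hp.star[0], hp.star[1], "+", 1.0),
    ]
    return call_duplex(fold, hits).verdict == "duplex"


# ---------------------------------------------------------------------------
# reference bundle

SPECIES_TAGS = ("species:spA", "species:spB")

_CONTAMINANT_SHAPES = {
    "rRNA": (3, 120),
    "tRNA": (4, 75),
    "snRNA": (3, 100),
    "piRNA_transposon": (3, 150),
    "endosymbiont": (1, 2000),
}


@dataclass
class ReferenceBundle:
    family_alignments: dict[str, list[str]]
    reference_sets: dict[str, ReferenceSet]


def build_reference_bundle(
    hairpins: list[PlantedHairpin], config: SimulationConfig, seed: int
) -> ReferenceBundle:
    """Reference inputs a real analysis would download: family alignments for
    the known families (the mature plus two near-identical orthologues),
    hairpin references with mature coordinates, contaminant sets, and
    other-species small-RNA sets containing the conserved novel matures.
    """
    rng = np.random.default_rng(seed)
    family_alignments: dict[str, list[str]] = {}
    hairpin_entries = []
    coords: dict[str, tuple[int, int]] = {}
    for hp in hairpins:
        if not hp.is_known:
            continue
        family = hp.family_tag.split(":", 1)[1]
        mature = hp.mature_seq
        orthologs = [mature]
        for _ in range(2):
            pos = int(rng.integers(len(mature)))
            alt = rng.choice([b for b in "ACGT" if b != mature[pos]])
            orthologs.append(mature[:pos] + alt + mature[pos + 1 :])
        family_alignments[family] = orthologs
        hairpin_entries.append((family, hp.sequence))
        coords[family] = hp.mature
    sets: dict[str, ReferenceSet] = {
        "hairpin": ReferenceSet("hairpin", hairpin_entries, mature_coords=coords)
    }
    for name, (n, length) in _CONTAMINANT_SHAPES.items():
        sets[name] = ReferenceSet(
            name, [(f"{name}{i + 1}", _random_seq(rng, length)) for i in range(n)]
        )
    conserved = [hp for hp in hairpins if hp.family_tag == "novel_conserved"]
    for si, tag in enumerate(SPECIES_TAGS):
        entries = []
        for ci, hp in enumerate(conserved):
            if ci % len(SPECIES_TAGS) in (si, (si + 1) % len(SPECIES_TAGS)):
                entries.append((f"{tag}_{hp.id}", hp.mature_seq))
        for d in range(5):  # unrelated decoy sequences
            entries.append((f"{tag}_decoy{d}", _random_seq(rng, 22)))
        sets[tag] = ReferenceSet(tag, entries)
    return ReferenceBundle(family_alignments=family_alignments, reference_sets=sets)


# ---------------------------------------------------------------------------
# library emission

def _variant_table(config: SimulationConfig) -> tuple[list[tuple[int, int, str]], np.ndarray]:
    """All (5' shift, 3' shift, tail) end-variants with their probabilities."""
    variants = []
    probs = []
    tails = [("", 1.0 - config.tail_add_prob)] + [
        (b, config.tail_add_prob * p) for b, p in config.tail_base_probs.items()
    ]
    for s5, p5 in config.shift_probs.items():
        for s3, p3 in config.shift_probs.items():
            for tail, pt in tails:
                variants.append((s5, s3, tail))
                probs.append(p5 * p3 * pt)
    return variants, np.array(probs)


def draw_base_counts(
    hairpins: list[PlantedHairpin], config: SimulationConfig, seed: int
) -> dict[str, tuple[int, float]]:
    """Library-independent locus expression: (mature count, star ratio) per hairpin."""
    rng = np.random.default_rng(seed)
    counts = _power_law_counts(
        rng, config.abundance_exponent, config.locus_min_count, config.locus_max_count,
        len(hairpins),
    )
    ratios = rng.uniform(*config.star_ratio_range, size=len(hairpins))
    return {hp.id: (int(c), float(r)) for hp, c, r in zip(hairpins, counts, ratios)}


def simulate_library(
    hairpins: list[PlantedHairpin],
    config: SimulationConfig,
    library: str,
    seed: int,
    base_counts: dict[str, tuple[int, float]] | None = None,
) -> tuple[list[ReadRecord], pd.DataFrame]:
    """Emit one library as collapsed unique reads plus an exact truth manifest.

    Counts are assigned at the unique-sequence level: each arm's reads are
    split multinomially over its end-variants, then artefact and contaminant
    reads are mixed in at the profile's fractions.
    """
    if library not in config.library_profiles:
        raise ValueError(f"unknown library profile {library!r}")
    profile = config.library_profiles[library]
    rng = np.random.default_rng(seed)
    if base_counts is None:
        base_counts = draw_base_counts(hairpins, config, seed)
    variants, vprobs = _variant_table(config)
    reads: dict[str, ReadRecord] = {}
    manifest_by_seq: dict[str, dict] = {}

    def emit(seq: str, count: int, origin: str, category: str) -> None:
        if count <= 0 or not seq:
            return
        rec = reads.get(seq)
        if rec is None:
            rid = f"{library[:2]}_{len(reads) + 1:06d}"
            reads[seq] = ReadRecord(id=rid, sequence=seq, counts={library: count})
            manifest_by_seq[seq] = {
                "sequence": seq, "origin": origin, "category": category, "count": count
            }
        else:
            rec.counts[library] += count
            manifest_by_seq[seq]["count"] += count

    planted_total = 0
    for hp in hairpins:
        base, star_ratio = base_counts[hp.id]
        mult = profile.known_multiplier if hp.is_known else profile.novel_multiplier
        jitter = float(np.exp(rng.normal(0.0, config.library_jitter_sigma)))
        for arm, interval, arm_count in (
            ("mature", hp.mature, int(round(base * mult * jitter))),
            ("star", hp.star, int(round(base * star_ratio * mult * jitter))),
        ):
            if arm_count <= 0:
                continue
            planted_total += arm_count
            split = rng.multinomial(arm_count, vprobs)
            category = (
                hp.family_tag if hp.is_known else f"novel:{hp.family_tag.split('_', 1)[1]}"
            )
            for (s5, s3, tail), n in zip(variants, split):
                if n == 0:
                    continue
                lo = interval[0] + s5
                hi = interval[1] + s3
                if lo < 0 or hi > len(hp.sequence) or hi - lo < 5:
                    continue
                seq = hp.sequence[lo:hi] + tail
                emit(seq, int(n), f"{hp.id}/{arm}", f"{category}/{arm}")

    denom = 1.0 - profile.artefact_fraction - profile.contaminant_fraction
    n_artefact = int(round(planted_total * profile.artefact_fraction / denom))
    n_contaminant = int(round(planted_total * profile.contaminant_fraction / denom))
    _emit_artefacts(rng, config, n_artefact, emit)
    _emit_contaminants(rng, config, n_contaminant, emit)

    out = sorted(reads.values(), key=lambda r: r.id)
    manifest = pd.DataFrame(list(manifest_by_seq.values()))
    if not manifest.empty:
        manifest = manifest.rename(columns={"count": f"reads_{library}"})
    return out, manifest


def _emit_artefacts(rng, config: SimulationConfig, n_reads: int, emit) -> None:
    # ~99% of artefact sequences are singletons
    emitted = 0
    body_len = config.artefact_length - 10
    while emitted < n_reads:
        chunk = max(1, min(20_000, n_reads - emitted))
        bodies = rng.choice(_BASES, size=(chunk, body_len))
        tail_is_t = rng.random((chunk, 10)) < config.artefact_tail_t_prob
        others = rng.choice(np.array(list("ACG")), size=(chunk, 10))
        for b in range(chunk):
            tail = "".join("T" if tail_is_t[b, i] else others[b, i] for i in range(10))
            seq = "".join(bodies[b]) + tail
            count = 1 if rng.random() < 0.99 else int(rng.integers(2, 6))
            count = min(count, n_reads - emitted)
            emit(seq, count, "artefact", "artefact")
            emitted += count
            if emitted >= n_reads:
                break


_CONTAMINANT_WEIGHTS = {
    "rRNA": 0.10, "tRNA": 0.06, "snRNA": 0.04, "piRNA_transposon": 0.50,
    "endosymbiont": 0.30,
}


def _emit_contaminants(rng, config: SimulationConfig, n_reads: int, emit) -> None:
    names = list(_CONTAMINANT_WEIGHTS)
    weights = np.array(list(_CONTAMINANT_WEIGHTS.values()))
    weights = weights / weights.sum()
    source = getattr(config, "_contaminant_sources", None)
    if source is None:
        # fragments need a sequence source; synthesise one per set if the
        # caller did not attach the reference bundle
        source = {
            name: ["".join(rng.choice(_BASES, size=shape[1]))]
            for name, shape in _CONTAMINANT_SHAPES.items()
        }
    emitted = 0
    while emitted < n_reads:
        name = str(rng.choice(names, p=weights))
        ref = source[name][int(rng.integers(len(source[name])))]
        frag_len = int(rng.integers(24, 31) if name == "piRNA_transposon" else rng.integers(19, 31))
        if frag_len >= len(ref):
            continue
        start = int(rng.integers(0, len(ref) - frag_len))
        seq = ref[start : start + frag_len]
        count = int(
            _power_law_counts(
                rng, config.contaminant_count_exponent, 1, config.contaminant_max_count, 1
            )[0]
        )
        count = min(count, n_reads - emitted)
        emit(seq, count, f"contaminant:{name}", "contaminant")
        emitted += count


def attach_contaminant_sources(config: SimulationConfig, bundle: ReferenceBundle) -> None:
    """Make contaminant fragments come from the bundle's reference sequences."""
    config._contaminant_sources = {  # type: ignore[attr-defined]
        name: [s for _, s in bundle.reference_sets[name].sequences]
        for name in _CONTAMINANT_SHAPES
    }


# ---------------------------------------------------------------------------
# contigs

def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Dinucleotide-preserving shuffle (random Eulerian walk on the base graph)."""
    if len(seq) < 3:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    for a in edges:
        rng.shuffle(edges[a])
    # Hierholzer walk from the original start: an Eulerian path is guaranteed
    stack = [seq[0]]
    path: list[str] = []
    while stack:
        v = stack[-1]
        if edges.get(v):
            stack.append(edges[v].pop())
        else:
            path.append(stack.pop())
    return "".join(reversed(path))


def generate_contig_db(
    hairpins: list[PlantedHairpin],
    config: SimulationConfig,
    seed: int,
    n_decoys: int = 20,
    flank_range: tuple[int, int] = (20, 60),
) -> list[Contig]:
    """Contigs embedding the novel precursors exactly, plus shuffled decoys.

    Each precursor-bearing contig is certified at generation: a duplex must
    be callable from the planted mature/star positions after embedding
    (random flanks are redrawn otherwise). Decoys are dinucleotide-preserving
    shuffles containing no planted mature sequence.
    """
    rng = np.random.default_rng(seed)
    contigs: list[Contig] = []
    matures = [hp.mature_seq for hp in hairpins]
    novel = [hp for hp in hairpins if not hp.is_known]
    for i, hp in enumerate(novel):
        for _attempt in range(50):
            left = _random_seq(rng, int(rng.integers(*flank_range)))
            right = _random_seq(rng, int(rng.integers(*flank_range)))
            seq = left + hp.sequence + right
            off = len(left)
            hits = [
                ContigHit("m", f"contig{i + 1}", off + hp.mature[0], off + hp.mature[1], "+", 1.0),
                ContigHit("s", f"contig{i + 1}", off + hp.star[0], off + hp.star[1], "+", 1.0),
            ]
            calls = find_duplexes([Contig(f"contig{i + 1}", seq)], hits)
            if calls and next(iter(calls.values())).verdict == "duplex":
                contigs.append(Contig(id=f"contig{i + 1}", sequence=seq, source_tags=(hp.id,)))
                break
        else:
            raise RuntimeError(f"could not embed precursor {hp.id} in a callable contig")
    for d in range(n_decoys):
        template = novel[d % len(novel)].sequence
        for _attempt in range(50):
            shuffled = dinucleotide_shuffle(template, rng)
            seq = _random_seq(rng, 30) + shuffled + _random_seq(rng, 30)
            if not any(m in seq or revcomp(m) in seq for m in matures):
                contigs.append(Contig(id=f"decoy{d + 1}", sequence=seq, source_tags=()))
                break
    return contigs


# ---------------------------------------------------------------------------
# qPCR

def simulate_qpcr(
    abundances: dict[str, float],
    config: SimulationConfig,
    seed: int,
    effect_map: dict[str, float] | None = None,
    reference_gene: str = "U6",
    reference_abundance: float = 1e6,
    noise_sd: float | None = None,
) -> pd.DataFrame:
    """Ct table for control/treated groups from true abundances.

    Ct = baseline - log_E(abundance) + Gaussian noise; the treated group's
    abundances are multiplied by the per-gene effect (e.g. 0.5 for a 2-fold
    knockdown). The reference gene is unaffected by effects. Genes with
    non-positive abundance are skipped with a warning.
    """
    rng = np.random.default_rng(seed)
    sd = config.qpcr_noise_sd if noise_sd is None else noise_sd
    effect_map = effect_map or {}
    log_e = np.log(config.qpcr_efficiency)
    rows = []
    genes = {reference_gene: reference_abundance, **abundances}
    for gene, abundance in genes.items():
        if abundance <= 0:
            logger.warning("gene %s has non-positive abundance, skipped", gene)
            continue
        effect = 1.0 if gene == reference_gene else effect_map.get(gene, 1.0)
        for group, level in (("control", abundance), ("treated", abundance * effect)):
            base_ct = config.qpcr_baseline_ct - np.log(level) / log_e
            for rep in range(1, config.qpcr_replicates + 1):
                ct = base_ct + (rng.normal(0.0, sd) if sd > 0 else 0.0)
                rows.append({"gene": gene, "group": group, "replicate": rep, "Ct": float(ct)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# one-call dataset

@dataclass
class SyntheticDataset:
    config: SimulationConfig
    seed: int
    hairpins: list[PlantedHairpin]
    bundle: ReferenceBundle
    base_counts: dict[str, tuple[int, float]]
    libraries: dict[str, list[ReadRecord]]
    manifest: pd.DataFrame
    contigs: list[Contig]

    def combined_reads(self) -> list[ReadRecord]:
        """One record per unique sequence with counts from every library."""
        from .preprocess import collapse_identical

        allreads = [r for recs in self.libraries.values() for r in recs]
        return collapse_identical(allreads)

    def planted_novel(self) -> list[PlantedHairpin]:
        return [hp for hp in self.hairpins if not hp.is_known]


def generate_dataset(config: SimulationConfig | None = None, seed: int = 0) -> SyntheticDataset:
    """Hairpins, references, both libraries, contigs and the merged manifest."""
    config = config or SimulationConfig()
    hairpins = generate_hairpin_set(config, seed)
    bundle = build_reference_bundle(hairpins, config, seed + 1)
    attach_contaminant_sources(config, bundle)
    base_counts = draw_base_counts(hairpins, config, seed + 2)
    libraries = {}
    manifests = []
    for i, label in enumerate(config.library_profiles):
        reads, manifest = simulate_library(
            hairpins, config, label, seed + 3 + i, base_counts=base_counts
        )
        libraries[label] = reads
        manifests.append(manifest.set_index(["sequence", "origin", "category"]))
    manifest = (
        pd.concat(manifests, axis=1).fillna(0).astype(int).reset_index()
    )
    contigs = generate_contig_db(hairpins, config, seed + 9)
    return SyntheticDataset(
        config=config, seed=seed, hairpins=hairpins, bundle=bundle,
        base_counts=base_counts, libraries=libraries, manifest=manifest, contigs=contigs,
    )
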