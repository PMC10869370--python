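"""Mutation catalogues, signature refitting and HRD classification.

Single-base substitutions are classified into the 96 trinucleotide-context
channels (pyrimidine-strand convention: a purine reference base is
reverse-complemented together with its flanks), and short indels into the
83 channels of the standard indel alphabet (1-bp insertions/deletions by
C/T homopolymer length, longer events by repeat-unit count, deletions at
microhomology by homology length).

An observed catalogue is then *refit* against a fixed set of reference
signatures: exposures ``e`` minimize ``|| S e - c ||_2`` subject to
``e >= 0`` and ``sum(e) = 1``, where ``c`` is the catalogue normalized to
proportions and the columns of ``S`` are the chosen reference signatures.
The problem is solved with a deterministic active-set nonnegative
least-squares on the system augmented with a heavily weighted sum-to-one
row, followed by exact renormalization — no random initialization, so the
fit is bit-reproducible.

Homologous recombination deficiency (HRD) is called from the refit:
positive when signature SBS3 exceeds 10% of the substitution profile or
ID6 exceeds 20% of the indel profile (strict inequalities).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib
import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .variants import VariantClass, VariantSite

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: SBS-96 channel labels, substitution-major (canonical plotting order).
SBS96_CHANNELS: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in _BASES
    for three in _BASES
)


def _id83_channels() -> tuple[str, ...]:
    ch: list[str] = []
    for base in "CT":
        ch += [f"1:Del:{base}:{i}" for i in range(6)]
    for base in "CT":
        ch += [f"1:Ins:{base}:{i}" for i in range(6)]
    for n in "2345":
        ch += [f"{n}:Del:R:{i}" for i in range(6)]
    for n in "2345":
        ch += [f"{n}:Ins:R:{i}" for i in range(6)]
    ch += ["2:Del:M:1"]
    ch += [f"3:Del:M:{i}" for i in (1, 2)]
    ch += [f"4:Del:M:{i}" for i in (1, 2, 3)]
    ch += [f"5:Del:M:{i}" for i in (1, 2, 3, 4, 5)]
    return tuple(ch)


#: ID-83 channel labels in the standard order.
ID83_CHANNELS: tuple[str, ...] = _id83_channels()
assert len(SBS96_CHANNELS) == 96 and len(ID83_CHANNELS) == 83

ALPHABETS: dict[str, tuple[str, ...]] = {
    "SBS96": SBS96_CHANNELS,
    "ID83": ID83_CHANNELS,
}

#: bp scanned on each side of an indel for repeat/microhomology context.
REPEAT_SEARCH_WINDOW = 100


class ReferenceMismatchError(ValueError):
    """The variant's REF allele disagrees with the reference sequence."""


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _fetch(reference, chrom: str, start0: int, end0: int) -> str:
    """Slice a reference sequence source (dict of str, pyfaidx.Fasta, ...)."""
    try:
        seq = reference[chrom]
    except KeyError as exc:
        raise KeyError(f"chromosome {chrom!r} not in reference") from exc
    start0 = max(0, start0)
    return str(seq[start0:end0]).upper()


# ---------------------------------------------------------------------------
# catalogue containers


@dataclass
class MutationCatalogue:
    """Mutation counts over a fixed channel alphabet."""

    alphabet: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        if self.alphabet not in ALPHABETS:
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(ALPHABETS[self.alphabet]),):
            raise ValueError(
                f"{self.alphabet} catalogue needs "
                f"{len(ALPHABETS[self.alphabet])} channels, "
                f"got {self.counts.shape}"
            )
        if (self.counts < 0).any():
            raise ValueError("catalogue counts must be nonnegative")

    @property
    def channels(self) -> tuple[str, ...]:
        return ALPHABETS[self.alphabet]

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def proportions(self) -> np.ndarray:
        if self.total == 0:
            raise ValueError("empty catalogue has no proportions")
        return self.counts / self.total

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"channel": self.channels, "count": self.counts.astype(int)}
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, alphabet: str | None = None):
        df = pd.read_csv(path, sep="\t")
        if alphabet is None:
            alphabet = "SBS96" if len(df) == 96 else "ID83"
        order = {c: i for i, c in enumerate(ALPHABETS[alphabet])}
        unknown = set(df["channel"]) - set(order)
        if unknown:
            raise ValueError(f"unknown channels in {path}: {sorted(unknown)[:5]}")
        counts = np.zeros(len(order))
        for ch, n in zip(df["channel"], df["count"]):
            counts[order[ch]] = n
        return cls(alphabet, counts)


@dataclass
class SignatureMatrix:
    """Reference signatures: per-channel probabilities, one column each."""

    alphabet: str
    names: tuple[str, ...]
    matrix: np.ndarray  # (n_channels, n_signatures)

    def __post_init__(self) -> None:
        self.names = tuple(self.names)
        self.matrix = np.asarray(self.matrix, dtype=float)
        n_ch = len(ALPHABETS[self.alphabet])
        if self.matrix.shape != (n_ch, len(self.names)):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{n_ch} channels x {len(self.names)} signatures"
            )
        if (self.matrix < 0).any():
            raise ValueError("signature probabilities must be nonnegative")
        sums = self.matrix.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-6):
            bad = [n for n, s in zip(self.names, sums) if abs(s - 1) > 1e-6]
            raise ValueError(f"signature columns must sum to 1: {bad}")

    def subset(self, names: Sequence[str]) -> "SignatureMatrix":
        unknown = [n for n in names if n not in self.names]
        if unknown:
            raise ValueError(f"unknown signature name(s): {unknown}")
        idx = [self.names.index(n) for n in names]
        return SignatureMatrix(self.alphabet, tuple(names), self.matrix[:, idx])

    @classmethod
    def from_tsv(cls, path: str | Path, alphabet: str) -> "SignatureMatrix":
        """Read a COSMIC-style TSV: first column channel labels, one column
        per signature.  Rows are reordered to the canonical channel order."""
        df = pd.read_csv(path, sep="\t")
        label_col = df.columns[0]
        df = df.set_index(label_col)
        channels = ALPHABETS[alphabet]
        missing = set(channels) - set(df.index)
        if missing:
            raise ValueError(
                f"{path}: missing {len(missing)} {alphabet} channels, "
                f"e.g. {sorted(missing)[:3]}"
            )
        df = df.loc[list(channels)]
        return cls(alphabet, tuple(df.columns), df.to_numpy(dtype=float))

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            self.matrix, index=list(ALPHABETS[self.alphabet]),
            columns=list(self.names),
        )
        df.index.name = "Type"
        df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# context classification


def classify_sbs_context(variant: VariantSite, reference) -> str:
    """SBS-96 channel of an SNV under the pyrimidine-strand convention."""
    if variant.variant_class is not VariantClass.SNV:
        raise ValueError(f"{variant.chrom}:{variant.pos}: not an SNV")
    i0 = variant.pos - 1
    tri = _fetch(reference, variant.chrom, i0 - 1, i0 + 2)
    if len(tri) != 3 or any(b not in _BASES for b in tri):
        raise ValueError(
            f"{variant.chrom}:{variant.pos}: context {tri!r} not classifiable"
        )
    if tri[1] != variant.ref.upper():
        raise ReferenceMismatchError(
            f"{variant.chrom}:{variant.pos}: reference base {tri[1]} "
            f"does not match REF allele {variant.ref}"
        )
    ref, alt = variant.ref.upper(), variant.alt.upper()
    five, three = tri[0], tri[2]
    if ref in "AG":  # purine: take the opposite strand
        ref, alt = _revcomp(ref), _revcomp(alt)
        five, three = _revcomp(tri[2]), _revcomp(tri[0])
    return f"{five}[{ref}>{alt}]{three}"


def _count_run(seq: str, base: str, reverse: bool = False) -> int:
    it = reversed(seq) if reverse else iter(seq)
    n = 0
    for b in it:
        if b != base:
            break
        n += 1
    return n


def _count_unit_copies(seq: str, unit: str, reverse: bool = False) -> int:
    """Full copies of ``unit`` tiled from one end of ``seq``."""
    L = len(unit)
    n = 0
    if reverse:
        while seq.endswith(unit):
            seq = seq[:-L]
            n += 1
    else:
        while seq.startswith(unit):
            seq = seq[L:]
            n += 1
    return n


def _shared_prefix(a: str, b: str) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return n


def classify_indel_context(variant: VariantSite, reference) -> str:
    """ID-83 channel of an insertion or deletion.

    Follows the standard decision tree: 1-bp events by the length of the
    C/T homopolymer they sit in (A/G deleted or inserted bases are
    complemented to T/C); longer events by the number of additional copies
    of the indel sequence in the +-100 bp flank; deletions with no flanking
    copy by the length of microhomology shared with the breakpoint flanks
    (repeat classification wins when both apply).
    """
    ref, alt = variant.ref.upper(), variant.alt.upper()
    k = _shared_prefix(ref, alt)
    if k == 0 or (len(ref) > k and len(alt) > k):
        raise ValueError(
            f"{variant.chrom}:{variant.pos}: not a simple anchored indel "
            f"({variant.ref}>{variant.alt})"
        )
    observed = _fetch(
        reference, variant.chrom, variant.pos - 1, variant.pos - 1 + len(ref)
    )
    if observed != ref:
        raise ReferenceMismatchError(
            f"{variant.chrom}:{variant.pos}: reference {observed!r} does not "
            f"match REF allele {ref!r}"
        )

    if len(ref) > len(alt):  # deletion of D at del0
        d = ref[k:]
        del0 = variant.pos - 1 + k
        left = _fetch(reference, variant.chrom, del0 - REPEAT_SEARCH_WINDOW, del0)
        right = _fetch(
            reference, variant.chrom, del0 + len(d),
            del0 + len(d) + REPEAT_SEARCH_WINDOW,
        )
        L = len(d)
        if L == 1:
            base = d
            run = _count_run(right, base) + _count_run(left, base, reverse=True)
            pyr = base.translate(_COMPLEMENT) if base in "AG" else base
            return f"1:Del:{pyr}:{min(run, 5)}"
        copies = _count_unit_copies(right, d) + _count_unit_copies(
            left, d, reverse=True
        )
        size = min(L, 5)
        if copies >= 1:
            return f"{size}:Del:R:{min(copies, 5)}"
        mh_fwd = _shared_prefix(d, right)
        mh_rev = _shared_prefix(d[::-1], left[::-1])
        mh = min(max(mh_fwd, mh_rev), L - 1, 5)
        if mh >= 1:
            return f"{size}:Del:M:{mh}"
        return f"{size}:Del:R:0"

    # insertion of D after ins0 (the last shared reference base)
    d = alt[k:]
    ins0 = variant.pos - 1 + k  # insertion sits between ins0-1 and ins0
    left = _fetch(reference, variant.chrom, ins0 - REPEAT_SEARCH_WINDOW, ins0)
    right = _fetch(reference, variant.chrom, ins0, ins0 + REPEAT_SEARCH_WINDOW)
    L = len(d)
    if L == 1:
        base = d
        run = _count_run(right, base) + _count_run(left, base, reverse=True)
        pyr = base.translate(_COMPLEMENT) if base in "AG" else base
        return f"1:Ins:{pyr}:{min(run, 5)}"
    copies = _count_unit_copies(right, d) + _count_unit_copies(
        left, d, reverse=True
    )
    return f"{min(L, 5)}:Ins:R:{min(copies, 5)}"


def build_catalogue(
    variants: Sequence[VariantSite],
    reference,
    alphabet: str,
) -> tuple[MutationCatalogue, list[str]]:
    """Count classifiable variants per channel.

    Returns the catalogue and a list of skip reasons (variants of the
    wrong class for the alphabet, unclassifiable contexts).  The catalogue
    total equals the number of classified variants.
    """
    channels = ALPHABETS[alphabet]
    order = {c: i for i, c in enumerate(channels)}
    counts = np.zeros(len(channels))
    skipped: list[str] = []
    for v in variants:
        try:
            if alphabet == "SBS96":
                if v.variant_class is not VariantClass.SNV:
                    skipped.append(
                        f"{v.chrom}:{v.pos} {v.ref}>{v.alt}: not an SNV"
                    )
                    continue
                ch = classify_sbs_context(v, reference)
            else:
                if v.variant_class not in (
                    VariantClass.INSERTION, VariantClass.DELETION
                ):
                    skipped.append(
                        f"{v.chrom}:{v.pos} {v.ref}>{v.alt}: not an indel"
                    )
                    continue
                ch = classify_indel_context(v, reference)
        except (ValueError, KeyError) as exc:
            skipped.append(str(exc))
            continue
        counts[order[ch]] += 1
    return MutationCatalogue(alphabet, counts), skipped


# ---------------------------------------------------------------------------
# refitting


@dataclass
class ExposureVector:
    """Simplex-constrained signature proportions plus fit residual."""

    names: tuple[str, ...]
    proportions: np.ndarray
    residual_norm: float

    def __post_init__(self) -> None:
        self.names = tuple(self.names)
        self.proportions = np.asarray(self.proportions, dtype=float)
        if (self.proportions < -1e-12).any():
            raise ValueError("exposures must be nonnegative")
        if abs(self.proportions.sum() - 1.0) > 1e-6:
            raise ValueError("exposures must sum to 1")

    def proportion(self, name: str) -> float:
        if name not in self.names:
            raise ValueError(
                f"signature {name!r} not among fitted signatures {self.names}"
            )
        return float(self.proportions[self.names.index(name)])

    def as_dict(self) -> dict[str, float]:
        return {n: float(p) for n, p in zip(self.names, self.proportions)}

    def as_display_dict(self, floor: float = 1e-4) -> dict[str, float]:
        """Human-readable view: exposures below ``floor`` shown as 0."""
        return {
            n: (float(p) if p >= floor else 0.0)
            for n, p in zip(self.names, self.proportions)
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "proportions": self.as_dict(),
                    "residual_norm": self.residual_norm,
                },
                indent=2,
                sort_keys=True,
            )
            + "\n"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "ExposureVector":
        obj = json.loads(Path(path).read_text())
        props = obj["proportions"]
        return cls(
            tuple(props), np.array(list(props.values()), dtype=float),
            float(obj.get("residual_norm", float("nan"))),
        )


_SUM_WEIGHT = 1e4  # weight of the sum-to-one row in the augmented NNLS


def refit_exposures(
    catalogue: MutationCatalogue,
    signatures: SignatureMatrix,
    subset: Sequence[str] | None = None,
) -> ExposureVector:
    """Least-squares refit of a catalogue onto reference signatures.

    Minimizes ``|| S e - c ||_2`` over the probability simplex, with ``c``
    the catalogue proportions.  Scale-invariant in the catalogue counts.
    """
    if catalogue.alphabet != signatures.alphabet:
        raise ValueError(
            f"catalogue alphabet {catalogue.alphabet} != signature alphabet "
            f"{signatures.alphabet}"
        )
    if catalogue.total == 0:
        raise ValueError("cannot refit an empty catalogue")
    sig = signatures if subset is None else signatures.subset(subset)
    c = catalogue.proportions()
    S = sig.matrix
    k = S.shape[1]
    A = np.vstack([S, np.full((1, k), _SUM_WEIGHT)])
    b = np.concatenate([c, [_SUM_WEIGHT]])
    e, _ = nnls(A, b)
    total = e.sum()
    if total <= 0:
        raise RuntimeError("degenerate refit: all exposures zero")
    e = e / total
    residual = float(np.linalg.norm(S @ e - c))
    return ExposureVector(sig.names, e, residual)


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


# ---------------------------------------------------------------------------
# HRD rule


@dataclass
class HRDRuleConfig:
    """Positivity thresholds on the SBS3 and ID6 exposures (strict >)."""

    sbs3_threshold: float = 0.10
    id6_threshold: float = 0.20

    def __post_init__(self) -> None:
        for name in ("sbs3_threshold", "id6_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")


@dataclass
class HRDCall:
    positive: bool
    reasons: list[str]
    sbs3: float
    id6: float

    @property
    def status(self) -> str:
        return "HRD_positive" if self.positive else "HRD_negative"


def _get_proportion(exposures, name: str) -> float:
    if isinstance(exposures, ExposureVector):
        return exposures.proportion(name)
    if isinstance(exposures, Mapping):
        if name not in exposures:
            raise ValueError(f"signature {name!r} missing from exposures")
        return float(exposures[name])
    raise TypeError(f"unsupported exposure container {type(exposures)!r}")


def hrd_classify(
    sbs_exposures,
    id_exposures,
    rule: HRDRuleConfig | None = None,
) -> HRDCall:
    """HRD verdict: SBS3 > 10% of substitutions OR ID6 > 20% of indels."""
    rule = rule or HRDRuleConfig()
    sbs3 = _get_proportion(sbs_exposures, "SBS3")
    id6 = _get_proportion(id_exposures, "ID6")
    reasons: list[str] = []
    if sbs3 > rule.sbs3_threshold:
        reasons.append(
            f"SBS3 proportion {sbs3:.3f} > {rule.sbs3_threshold:.2f}"
        )
    if id6 > rule.id6_threshold:
        reasons.append(f"ID6 proportion {id6:.3f} > {rule.id6_threshold:.2f}")
    return HRDCall(bool(reasons), reasons, sbs3, id6)


# ---------------------------------------------------------------------------
# plotting

_SBS_GROUP_COLORS = (
    "#03bcee", "#010101", "#e32926", "#cac9c9", "#a1ce63", "#ebc6c4",
)


def _id83_block_edges() -> list[int]:
    edges, i = [], 0
    for width in (6, 6, 6, 6, 6, 6, 6, 6, 6, 6, 6, 6, 1, 2, 3, 5):
        i += width
        edges.append(i)
    return edges[:-1]


def catalogue_profile_plot(
    catalogue: MutationCatalogue,
    reference_signature: np.ndarray | None = None,
    reference_name: str = "reference",
    path: str | Path | None = None,
) -> "plt.Figure":
    """Bar profile of a catalogue, optionally against a reference signature.

    With a reference panel the cosine similarity between the catalogue
    proportions and the reference is annotated.
    """
    n_panels = 2 if reference_signature is not None else 1
    fig, axes = plt.subplots(
        n_panels, 1, figsize=(12, 2.8 * n_panels), squeeze=False
    )
    x = np.arange(len(catalogue.channels))
    if catalogue.alphabet == "SBS96":
        colors = [
            _SBS_GROUP_COLORS[i // 16] for i in range(96)
        ]
        seps = [16 * i for i in range(1, 6)]
    else:
        colors = ["#5b8bd0"] * 83
        seps = _id83_block_edges()

    def draw(ax, values, title):
        ax.bar(x, values, color=colors, width=0.8)
        for s in seps:
            ax.axvline(s - 0.5, color="grey", lw=0.5, alpha=0.6)
        ax.set_xlim(-1, len(x))
        ax.set_title(title, fontsize=10)
        ax.set_xticks([])

    draw(axes[0][0], catalogue.counts, f"{catalogue.alphabet} catalogue")
    if reference_signature is not None:
        ref = np.asarray(reference_signature, dtype=float)
        draw(axes[1][0], ref, reference_name)
        cos = cosine_similarity(catalogue.counts, ref)
        axes[0][0].text(
            0.99, 0.92, f"cosine similarity to {reference_name}: {cos:.3f}",
            transform=axes[0][0].transAxes, ha="right", fontsize=9,
        )
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
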