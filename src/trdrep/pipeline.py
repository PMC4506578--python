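"""End-to-end glue: simulate -> annotate -> clonotype for a whole study."""

from __future__ import annotations

from dataclasses import dataclass, field

from .annotate import AnnotateConfig, AnnotatedRead, annotate_counter
from .clonotype import ClonotypeTable, enumerate_clonotypes
from .germline import GermlineReference, default_reference
from .simulate import CloneTable, SimParams, read_counter, simulate_repertoire


@dataclass
class StudyResult:
    clone_table: CloneTable  # simulator ground truth
    annotated: dict[str, list[tuple[AnnotatedRead, int]]]
    clonotypes: dict[str, ClonotypeTable]
    config: AnnotateConfig = field(default_factory=AnnotateConfig)


def annotate_sample(
    counts: dict[str, int],
    sample_id: str,
    ref: GermlineReference,
    config: AnnotateConfig = AnnotateConfig(),
) -> tuple[list[tuple[AnnotatedRead, int]], ClonotypeTable]:
    annotated = annotate_counter(counts, ref, config)
    return annotated, enumerate_clonotypes(annotated, sample_id)


def run_study(
    params: SimParams,
    ref: GermlineReference | None = None,
    config: AnnotateConfig = AnnotateConfig(),
) -> StudyResult:
    """Simulate the cohort and push every sample through annotation and
    clonotype enumeration (reads handled as deduplicated multisets)."""
    ref = ref or default_reference()
    clone_table = simulate_repertoire(params, ref)
    annotated: dict[str, list[tuple[AnnotatedRead, int]]] = {}
    clonotypes: dict[str, ClonotypeTable] = {}
    for sid in clone_table.sample_ids:
        counts = read_counter(clone_table, sid, ref)
        annotated[sid], clonotypes[sid] = annotate_sample(counts, sid, ref, config)
    return StudyResult(clone_table, annotated, clonotypes, config)
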