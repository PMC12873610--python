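"""Prompt assembly and robust parsing of structured model output.

Prompts follow a fixed section order — role statement, task definition and
context, output-schema definition (with the explanation field first, so the
model reasons before it answers), few-shot examples (five by default), then
the target abstract — and are byte-stable for snapshot testing.

Parsing is a *total* function into :class:`~quorum.core.RaterAnswer`: any
malformed model text yields status FORMAT_ISSUE, never an exception.  The
parser locates the first balanced JSON object in the text (tolerating
surrounding prose and code fences), validates the answer field and
canonicalizes the value — case-folded labels with a configurable synonym
list, thousands-separator-free non-negative integers, and a configurable set
of "missing" spellings.  Word numerals ("two hundred") are deliberately not
parsed: exact-match consensus wants conservative normalization.

Live model invocation is out of scope: a rater is any callable mapping
abstract text to raw output text, and sampling parameters are pass-through
provenance, not behaviour.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from typing import Any, Callable, Optional, Sequence, Union

from .core import (
    DEFAULT_LABELS,
    MISSING,
    RaterAnswer,
    Status,
    TaskKind,
)

__all__ = [
    "PromptSpec",
    "RawModelOutput",
    "build_prompt",
    "find_structured_object",
    "extract_structured",
    "normalize_answer",
    "serialize_answer",
    "DEFAULT_SYNONYMS",
    "DEFAULT_MISSING_TOKENS",
    "ANSWER_FIELDS",
]

log = logging.getLogger(__name__)

#: Label spellings folded onto the canonical label set.
DEFAULT_SYNONYMS = {
    "non-drug": "nondrug",
    "non drug": "nondrug",
    "non_drug": "nondrug",
}

#: Strings treated as the MISSING token for extraction answers.
DEFAULT_MISSING_TOKENS = (
    "missing", "not reported", "not_reported", "none", "null", "na", "n/a", "",
)

#: Default answer-field name per task in the output schema.
ANSWER_FIELDS = {
    TaskKind.CATEGORICAL: "classification",
    TaskKind.EXTRACTION: "n_randomized",
}


@dataclass(frozen=True)
class PromptSpec:
    """The prompt recipe for one task.

    The output schema is an ordered field list whose first entry is the
    explanation field; the answer field must come after it.  Few-shot
    examples are (abstract text, structured output) pairs validated against
    the schema.
    """

    role_statement: str
    task_context: str
    answer_field: str
    output_schema: tuple = ()
    few_shot_examples: tuple = ()
    explanation_field: str = "explanation"

    def __post_init__(self) -> None:
        schema = tuple(self.output_schema) or (
            self.explanation_field, self.answer_field)
        object.__setattr__(self, "output_schema", schema)
        if self.explanation_field not in schema or self.answer_field not in schema:
            raise ValueError(
                "output schema must contain the explanation and answer fields")
        if schema.index(self.explanation_field) >= schema.index(self.answer_field):
            raise ValueError(
                "the explanation field must precede the answer field "
                "(reason first, then answer)")
        examples = tuple(
            (str(abstract), dict(output))
            for abstract, output in self.few_shot_examples
        )
        for _, output in examples:
            if set(output) != set(schema):
                raise ValueError(
                    f"few-shot example fields {sorted(output)} do not match "
                    f"the output schema {list(schema)}")
        object.__setattr__(self, "few_shot_examples", examples)


@dataclass(frozen=True)
class RawModelOutput:
    """Untrusted free text as returned by a model for one item."""

    rater_id: str
    item_id: str
    text: str


def _example_block(spec: PromptSpec, abstract: str, output: dict) -> str:
    ordered = {k: output[k] for k in spec.output_schema}
    return (f"Abstract:\n{abstract}\n"
            f"Output:\n{json.dumps(ordered, ensure_ascii=False)}")


def build_prompt(spec: PromptSpec, abstract: str) -> str:
    """Deterministic prompt assembly in the fixed section order; identical
    inputs produce identical bytes."""
    if not abstract or not abstract.strip():
        raise ValueError("abstract text must be non-empty")
    schema_fields = ", ".join(f'"{f}"' for f in spec.output_schema)
    sections = [
        spec.role_statement.strip(),
        spec.task_context.strip(),
        ("Answer with a single JSON object containing, in order, the fields "
         f"{schema_fields}. Give your reasoning in "
         f'"{spec.explanation_field}" before the answer in '
         f'"{spec.answer_field}".'),
    ]
    if spec.few_shot_examples:
        sections.append("Examples:")
        for ex_abstract, ex_output in spec.few_shot_examples:
            sections.append(_example_block(spec, ex_abstract, ex_output))
    sections.append(f"Abstract:\n{abstract.strip()}\nOutput:")
    return "\n\n".join(sections)


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------


def find_structured_object(text: str) -> Optional[dict]:
    """First balanced, JSON-parseable object in free text, or None.

    Scans brace-by-brace with string/escape awareness, so prose and code
    fences around the object are harmless.  When several objects parse, the
    first is used and the surplus is logged.
    """
    candidates = []
    i, n = 0, len(text)
    while i < n:
        if text[i] != "{":
            i += 1
            continue
        depth = 0
        in_string = False
        escape = False
        for j in range(i, n):
            ch = text[j]
            if in_string:
                if escape:
                    escape = False
                elif ch == "\\":
                    escape = True
                elif ch == '"':
                    in_string = False
                continue
            if ch == '"':
                in_string = True
            elif ch == "{":
                depth += 1
            elif ch == "}":
                depth -= 1
                if depth == 0:
                    candidates.append((i, j + 1))
                    break
        i = candidates[-1][1] if candidates and candidates[-1][0] == i else i + 1
    parsed = []
    for start, end in candidates:
        try:
            obj = json.loads(text[start:end])
        except json.JSONDecodeError:
            continue
        if isinstance(obj, dict):
            parsed.append(obj)
    if len(parsed) > 1:
        log.debug("multiple structured objects found; using the first")
    return parsed[0] if parsed else None


def normalize_answer(
    raw_value: Any,
    task: Union[TaskKind, str],
    labels: Sequence[str] = DEFAULT_LABELS,
    synonyms: Optional[dict] = None,
    missing_tokens: Sequence[str] = DEFAULT_MISSING_TOKENS,
) -> Optional[Union[str, int]]:
    """Canonicalize one raw answer value; None signals normalization failure
    (a value, not an exception — the caller records FORMAT_ISSUE).

    CATEGORICAL: case-insensitive match onto the label set after synonym
    folding.  EXTRACTION: strips thousands separators and whitespace and
    parses a non-negative integer; the configured missing spellings map to
    :data:`~quorum.core.MISSING`.
    """
    task = TaskKind(task)
    if raw_value is None:
        return None
    if task is TaskKind.CATEGORICAL:
        if not isinstance(raw_value, str):
            return None
        s = raw_value.strip().lower()
        s = (synonyms or DEFAULT_SYNONYMS).get(s, s)
        return s if s in labels else None
    # extraction
    if isinstance(raw_value, bool):
        return None
    if isinstance(raw_value, int):
        return raw_value if raw_value >= 0 else None
    if isinstance(raw_value, float):
        return int(raw_value) if raw_value.is_integer() and raw_value >= 0 else None
    if not isinstance(raw_value, str):
        return None
    s = raw_value.strip().lower()
    if s in missing_tokens:
        return MISSING
    s = re.sub(r"[,\s_']", "", s)
    if re.fullmatch(r"\d+", s):
        return int(s)
    return None


def extract_structured(
    output: Union[RawModelOutput, str],
    task: Union[TaskKind, str],
    answer_field: Optional[str] = None,
    rater_id: str = "",
    item_id: str = "",
    **normalize_kwargs,
) -> RaterAnswer:
    """Parse raw model text into a :class:`RaterAnswer` — total on text.

    Any failure (no balanced object, missing answer field, un-normalizable
    value) yields status FORMAT_ISSUE; only programmer errors (an unknown
    task kind) raise.
    """
    task = TaskKind(task)
    if isinstance(output, RawModelOutput):
        rater_id, item_id, text = output.rater_id, output.item_id, output.text
    else:
        text = output
    field_name = answer_field or ANSWER_FIELDS[task]

    def failure() -> RaterAnswer:
        return RaterAnswer(item_id=item_id, rater_id=rater_id, task=task,
                           status=Status.FORMAT_ISSUE)

    if not isinstance(text, str):
        return failure()
    obj = find_structured_object(text)
    if obj is None or field_name not in obj:
        return failure()
    value = normalize_answer(obj[field_name], task, **normalize_kwargs)
    if value is None:
        return failure()
    rationale = obj.get("explanation")
    if not isinstance(rationale, str) or not rationale:
        rationale = None
    return RaterAnswer(item_id=item_id, rater_id=rater_id, task=task,
                       status=Status.VALID, value=value, rationale=rationale)


def serialize_answer(
    answer: RaterAnswer,
    answer_field: Optional[str] = None,
    explanation_field: str = "explanation",
) -> str:
    """Render a VALID answer in the output schema (round-trips through
    :func:`extract_structured`)."""
    if answer.status is not Status.VALID:
        raise ValueError("only VALID answers serialize into the output schema")
    field_name = answer_field or ANSWER_FIELDS[answer.task]
    obj = {explanation_field: answer.rationale or "",
           field_name: answer.value}
    return json.dumps(obj, ensure_ascii=False)


#: A live rater is any callable mapping abstract text to raw output text.
#: Sampling parameters (temperature, top_p, top_k) travel as provenance
#: metadata alongside the callable; the core never interprets them.
RaterCallable = Callable[[str], str]
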