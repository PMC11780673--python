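"""Model backends: the contract is ``complete(prompt, temperature) -> raw text``.

Tests and simulations use :class:`MockBackend`, which is hermetic and
fully determined by its seed: the verdict pattern for a prompt is a hash
of (seed, prompt), and repeated calls at temperature > 0 flip answers at
a rate proportional to the temperature, so the output distribution over
repeated runs depends only on (seed, temperature). The OpenAI-compatible
adapter is optional and never required for analysis.
"""

from __future__ import annotations

import hashlib
import json
from typing import Protocol

from .prompting import PromptSpec


class Backend(Protocol):
    def complete(self, prompt: str, temperature: float) -> str: ...


def _bits(*parts: object) -> int:
    h = hashlib.sha256("|".join(str(p) for p in parts).encode()).digest()
    return int.from_bytes(h[:8], "big")


class MockBackend:
    """Deterministic stand-in model producing well-formed structured output.

    The base answer per (prompt, sign) is pseudo-random from the seed; at
    temperature T each repeated call independently flips an answer with
    probability ``flip_scale * T``. Citations quote a short span of the
    prompt so downstream citation parsing has something realistic to chew
    on. An internal per-(prompt, temperature) counter makes repeated calls
    distinct yet bit-identically reproducible for a fixed seed.
    """

    def __init__(self, seed: int = 0, spec: PromptSpec = PromptSpec(), flip_scale: float = 0.05):
        self.seed = seed
        self.spec = spec
        self.flip_scale = flip_scale
        self._counts: dict[tuple[str, float], int] = {}

    def complete(self, prompt: str, temperature: float) -> str:
        key = (prompt, temperature)
        call = self._counts.get(key, 0)
        self._counts[key] = call + 1
        out = {}
        for sign in self.spec.signs:
            base = _bits(self.seed, prompt, sign) % 100 < 20  # ~20% base true rate
            flip_draw = _bits(self.seed, prompt, sign, temperature, call) % 10**6
            answer = (not base) if flip_draw < self.flip_scale * temperature * 10**6 else base
            citation = ""
            if answer:
                # quote a plausible span from the prompt body
                lines = [ln for ln in prompt.splitlines() if sign in ln.lower()]
                citation = f'"{lines[0].strip()}"' if lines else ""
            out[sign] = {"answer": answer, "citation": citation}
        return json.dumps(out)


class FailingBackend:
    """Test double that raises for configured prompts (by substring)."""

    def __init__(self, inner: Backend, fail_if_contains: str):
        self.inner = inner
        self.fail_if_contains = fail_if_contains

    def complete(self, prompt: str, temperature: float) -> str:
        if self.fail_if_contains in prompt:
            raise ConnectionError("simulated transport failure")
        return self.inner.complete(prompt, temperature)


class OpenAIBackend:
    """Adapter for an OpenAI-compatible chat-completion endpoint.

    Optional: constructing it requires the ``openai`` package and
    credentials in the environment; nothing else in the package imports
    or needs it.
    """

    def __init__(self, model: str, **client_kwargs):
        try:
            from openai import OpenAI  # type: ignore[import-not-found]
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError(
                "the 'openai' package is required for the live backend; "
                "install it or use the mock backend"
            ) from exc
        self._client = OpenAI(**client_kwargs)
        self.model = model

    def complete(self, prompt: str, temperature: float) -> str:  # pragma: no cover - live
        resp = self._client.chat.completions.create(
            model=self.model,
            temperature=temperature,
            messages=[{"role": "user", "content": prompt}],
        )
        return resp.choices[0].message.content or ""
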