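"""Named model registry used by the CLI and config loader."""

from __future__ import annotations

from typing import Callable

from .errors import ConfigError
from .experiment import Model
from .models.analytic import (
    constant_model,
    ishigami_model,
    linear_model,
    product_model,
)
from .models.predator_prey import pp_model
from .models.t4ss import t4_model

_REGISTRY: dict[str, Callable[[], Model]] = {
    "predator_prey": pp_model,
    "t4ss_pool": t4_model,
    "fx_linear": linear_model,
    "fx_ishigami": ishigami_model,
    "fx_constant": constant_model,
    "fx_product": product_model,
}


def list_models() -> list[str]:
    return sorted(_REGISTRY)


def get_model(name: str) -> Model:
    try:
        factory = _REGISTRY[name]
    except KeyError:
        raise ConfigError(
            f"unknown model {name!r}; registered models: {', '.join(list_models())}"
        ) from None
    return factory()
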