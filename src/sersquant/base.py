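"""Minimal estimator base following scikit-learn parameter conventions.

Estimators expose ``get_params``/``set_params`` driven by their ``__init__``
signature so they compose with scikit-learn pipelines and ``clone`` without
making scikit-learn a runtime dependency.
"""

from __future__ import annotations

import inspect
from typing import Any


class BaseEstimator:
    """Parameter handling shared by all sersquant estimators."""

    @classmethod
    def _param_names(cls) -> list[str]:
        sig = inspect.signature(cls.__init__)
        return [
            name
            for name, p in sig.parameters.items()
            if name != "self" and p.kind not in (p.VAR_POSITIONAL, p.VAR_KEYWORD)
        ]

    def get_params(self, deep: bool = True) -> dict[str, Any]:
        return {name: getattr(self, name) for name in self._param_names()}

    def set_params(self, **params: Any) -> "BaseEstimator":
        valid = set(self._param_names())
        for key, value in params.items():
            if key not in valid:
                raise ValueError(
                    f"Invalid parameter {key!r} for {type(self).__name__}; "
                    f"valid parameters are {sorted(valid)}"
                )
            setattr(self, key, value)
        return self

    def __repr__(self) -> str:
        params = ", ".join(f"{k}={v!r}" for k, v in self.get_params().items())
        return f"{type(self).__name__}({params})"


def check_fitted(estimator: Any, attr: str) -> None:
    if not hasattr(estimator, attr):
        raise RuntimeError(
            f"{type(estimator).__name__} is not fitted; call fit() first"
        )
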