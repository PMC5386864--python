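"""Minimal scikit-learn-compatible estimator base.

Implements the get_params/set_params protocol by introspecting ``__init__``
keyword parameters, which is what sklearn's ``clone``, ``Pipeline`` and the
model-selection utilities require.  Estimators here duck-type the sklearn
API rather than subclassing it, so the library itself has no sklearn
dependency.
"""

from __future__ import annotations

import inspect
from typing import Any

__all__ = ["BaseEstimator"]


class BaseEstimator:
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

    def set_params(self, **params: Any):
        valid = set(self._param_names())
        for key, value in params.items():
            if key not in valid:
                raise ValueError(
                    f"invalid parameter {key!r} for estimator "
                    f"{type(self).__name__}; valid parameters: {sorted(valid)}"
                )
            setattr(self, key, value)
        return self

    def __repr__(self) -> str:
        params = ", ".join(f"{k}={v!r}" for k, v in self.get_params().items())
        return f"{type(self).__name__}({params})"

    def __sklearn_tags__(self):
        # delegate to sklearn's default tags when sklearn is installed, so
        # the estimators compose with Pipeline; the library itself does not
        # depend on sklearn
        from sklearn.base import BaseEstimator as _SkBase

        return _SkBase.__sklearn_tags__(self)

    def _check_is_fitted(self, attr: str) -> None:
        if not hasattr(self, attr):
            raise RuntimeError(
                f"{type(self).__name__} instance is not fitted yet; call fit first"
            )
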