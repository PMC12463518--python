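"""Minimal process-based discrete-event simulation core.

A deliberately small engine: an event heap, generator-based processes,
FIFO resources with integer capacity, and an all-of join.  Time is a
float in arbitrary units (the simulator uses minutes).
"""

from __future__ import annotations

import heapq
from collections import deque
from typing import Callable, Generator, Iterable, Optional


class Event:
    """A one-shot event.  Callbacks fire, in order, when the event is
    popped from the environment's heap."""

    __slots__ = ("env", "callbacks", "value", "_scheduled")

    def __init__(self, env: "Environment"):
        self.env = env
        self.callbacks: Optional[list] = []
        self.value = None
        self._scheduled = False

    @property
    def processed(self) -> bool:
        return self.callbacks is None

    def succeed(self, value=None, delay: float = 0.0) -> "Event":
        if self._scheduled:
            raise RuntimeError("event already triggered")
        self._scheduled = True
        self.value = value
        self.env._schedule(self, delay)
        return self

    def subscribe(self, callback: Callable[["Event"], None]) -> None:
        """Attach *callback*; if the event already fired, run it at the
        current simulation time (value preserved via a proxy)."""
        if self.callbacks is None:
            proxy = Event(self.env)
            proxy.succeed(self.value)
            proxy.callbacks.append(callback)
        else:
            self.callbacks.append(callback)


class Timeout(Event):
    """Event that fires after a fixed nonnegative delay."""

    __slots__ = ()

    def __init__(self, env: "Environment", delay: float):
        if delay < 0:
            raise ValueError(f"negative delay {delay!r}")
        super().__init__(env)
        self._scheduled = True
        env._schedule(self, delay)


class Process(Event):
    """Wraps a generator; resumed each time the yielded event fires.
    Fires itself (with the generator's return value) on exhaustion."""

    __slots__ = ("_gen",)

    def __init__(self, env: "Environment", gen: Generator):
        super().__init__(env)
        self._gen = gen
        start = Event(env)
        start.succeed(None)
        start.callbacks.append(self._resume)

    def _resume(self, evt: Event) -> None:
        try:
            target = self._gen.send(evt.value)
        except StopIteration as stop:
            self.succeed(stop.value)
            return
        if not isinstance(target, Event):
            raise TypeError(f"process yielded non-event {target!r}")
        target.subscribe(self._resume)


class AllOf(Event):
    """Fires once every event in the collection has fired."""

    __slots__ = ("_pending",)

    def __init__(self, env: "Environment", events: Iterable[Event]):
        super().__init__(env)
        events = list(events)
        self._pending = len(events)
        if self._pending == 0:
            self.succeed()
            return
        for evt in events:
            evt.subscribe(self._on_fire)

    def _on_fire(self, evt: Event) -> None:
        self._pending -= 1
        if self._pending == 0:
            self.succeed()


class Environment:
    """Event loop: a heap of (time, seq, event)."""

    def __init__(self):
        self.now: float = 0.0
        self._heap: list = []
        self._seq = 0

    def _schedule(self, event: Event, delay: float = 0.0) -> None:
        heapq.heappush(self._heap, (self.now + delay, self._seq, event))
        self._seq += 1

    def timeout(self, delay: float) -> Timeout:
        return Timeout(self, delay)

    def process(self, gen: Generator) -> Process:
        return Process(self, gen)

    def all_of(self, events: Iterable[Event]) -> AllOf:
        return AllOf(self, events)

    def event(self) -> Event:
        return Event(self)

    def run(self, until: Optional[float] = None) -> None:
        """Process events in time order; stop after the last event at or
        before *until* (events exactly at the horizon are processed)."""
        while self._heap:
            t = self._heap[0][0]
            if until is not None and t > until:
                break
            _, _, evt = heapq.heappop(self._heap)
            self.now = t
            callbacks, evt.callbacks = evt.callbacks, None
            for cb in callbacks:
                cb(evt)
        if until is not None and self.now < until:
            self.now = until


class Resource:
    """Capacity-constrained resource with a FIFO request queue.

    ``request()`` returns an event that fires when a unit is granted;
    the holder must call ``release()`` exactly once per grant.
    """

    def __init__(self, env: Environment, capacity: int, name: str = ""):
        if capacity < 0:
            raise ValueError(f"negative capacity for {name or 'resource'}")
        self.env = env
        self.capacity = int(capacity)
        self.name = name
        self.users = 0
        self.peak_users = 0
        self.queue: deque = deque()
        self.max_queue = 0

    def request(self) -> Event:
        evt = Event(self.env)
        if self.users < self.capacity:
            self.users += 1
            self.peak_users = max(self.peak_users, self.users)
            evt.succeed()
        else:
            self.queue.append(evt)
            self.max_queue = max(self.max_queue, len(self.queue))
        return evt

    def release(self) -> None:
        if self.queue and self.users <= self.capacity:
            # hand the unit straight to the head of the queue
            self.queue.popleft().succeed()
        else:
            self.users -= 1

    def set_capacity(self, capacity: int) -> None:
        """Adjust capacity mid-run (shift change).  A shrink below the
        in-use count drains naturally as holders release."""
        self.capacity = int(capacity)
        while self.queue and self.users < self.capacity:
            self.users += 1
            self.peak_users = max(self.peak_users, self.users)
            self.queue.popleft().succeed()
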