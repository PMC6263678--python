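"""Sensing + transmission energy model and battery-usage calculator.

The resource-efficiency argument for the noise sensor is an energy budget:
per second of operation a device spends its sensing energy plus the energy
to radio the data it produced, where transmission energy scales with data
volume over link speed:

    E_total = E_sense + (data_KB_per_s / link_KB_per_s) * E_radio

Battery life in hours is the battery's energy (capacity_mAh x 3.6 x V,
joules) divided by E_total, divided by 3600.  With the published device
constants the noise sensor outlasts the sound sensor by roughly a factor
of ten at a 300 KB/s link.

Sensing energies are the devices' published per-second joule figures, not
a V x I recomputation (the two disagree for the Wi-Fi radio: 3.3 V x
170 mA = 0.561 W vs the published 0.5 J/s); ``volts_times_amps`` exposes
the cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .datamodel import ValidationError

#: Printed-table display convention: transmission joules are *ceiled* to 3
#: decimals (a conservative energy estimate; plain rounding would print
#: 0.000 for the noise sensor on the fastest link, where the table shows
#: 0.001), totals are sensing + ceiled transmission, and hours are floored
#: to 1 decimal.


def _ceil3(x: float) -> float:
    """Ceiling to 3 decimals, guarding float representation error."""
    return math.ceil(round(x * 1000.0, 9)) / 1000.0


@dataclass(frozen=True)
class DevicePowerSpec:
    """Electrical constants of one device.

    ``energy_J_per_s`` is the canonical published per-second sensing (or
    radio) energy; ``data_KB_per_s`` the data volume generated per second
    of sensing (0 for a radio).
    """

    name: str
    current_mA: float
    voltage_V: float
    energy_J_per_s: float
    data_KB_per_s: float = 0.0

    def __post_init__(self) -> None:
        if self.energy_J_per_s <= 0:
            raise ValidationError("energy_J_per_s must be positive")
        if self.data_KB_per_s < 0:
            raise ValidationError("data_KB_per_s must be nonnegative")

    def volts_times_amps(self) -> float:
        """V x I in watts — cross-check against the published J/s figure."""
        return self.voltage_V * self.current_mA / 1000.0


#: Published device constants: a WAV-recording sound sensor, the
#: peak-to-peak noise sensor (including its microcontroller), and the
#: Wi-Fi radio.
SOUND_SENSOR = DevicePowerSpec("sound", current_mA=180.0, voltage_V=5.0,
                               energy_J_per_s=0.9, data_KB_per_s=66.4)
NOISE_SENSOR = DevicePowerSpec("noise", current_mA=20.0, voltage_V=5.0,
                               energy_J_per_s=0.1, data_KB_per_s=0.9)
WIFI_RADIO = DevicePowerSpec("wifi", current_mA=170.0, voltage_V=3.3,
                             energy_J_per_s=0.5)

#: Link speeds (KB/s) used in the published comparison.
LINK_SPEEDS_KB_S = (300.0, 600.0, 900.0, 1200.0)


@dataclass(frozen=True)
class BatterySpec:
    """A battery: capacity in mAh and terminal voltage."""

    capacity_mAh: float = 400.0
    voltage_V: float = 5.0

    def __post_init__(self) -> None:
        if self.capacity_mAh < 0 or self.voltage_V <= 0:
            raise ValidationError("battery fields must be positive")


def battery_energy(battery: BatterySpec) -> float:
    """Total battery energy in joules: capacity_mAh x 3.6 x voltage.

    The default 400 mAh / 5 V wearable battery holds 7200 J.
    """
    return battery.capacity_mAh * 3.6 * battery.voltage_V


def transmission_energy(data_KB_per_s: float, link_speed_KB_s: float,
                        radio_energy_J_per_s: float = WIFI_RADIO.energy_J_per_s,
                        ) -> float:
    """Joules spent radioing one second's worth of sensed data."""
    if link_speed_KB_s <= 0:
        raise ValidationError("link speed must be positive")
    return data_KB_per_s / link_speed_KB_s * radio_energy_J_per_s


@dataclass(frozen=True)
class EnergyBreakdown:
    """Per-second energy budget of one device at one link speed."""

    device: str
    link_speed_KB_s: float
    sensing_J_per_s: float
    transmission_J_per_s: float
    battery_hours: float | None = None

    @property
    def total_J_per_s(self) -> float:
        return self.sensing_J_per_s + self.transmission_J_per_s

    @property
    def transmission_J_per_s_printed(self) -> float:
        """Transmission ceiled to 3 decimals (display convention)."""
        return _ceil3(self.transmission_J_per_s)

    @property
    def total_J_per_s_printed(self) -> float:
        """Total built from the printed transmission value — the
        convention the published table follows (0.9 + 0.056 = 0.956)."""
        return round(self.sensing_J_per_s
                     + self.transmission_J_per_s_printed, 3)

    @property
    def battery_hours_display(self) -> float | None:
        """Battery life floored to one decimal, the table's display form."""
        if self.battery_hours is None:
            return None
        return math.floor(self.battery_hours * 10.0) / 10.0


def total_energy(device: DevicePowerSpec, link_speed_KB_s: float,
                 radio: DevicePowerSpec = WIFI_RADIO) -> EnergyBreakdown:
    """Sensing + transmission budget for one device at one link speed."""
    tx = transmission_energy(device.data_KB_per_s, link_speed_KB_s,
                             radio.energy_J_per_s)
    return EnergyBreakdown(device=device.name, link_speed_KB_s=link_speed_KB_s,
                           sensing_J_per_s=device.energy_J_per_s,
                           transmission_J_per_s=tx)


def battery_hours(breakdown: EnergyBreakdown,
                  battery: BatterySpec = BatterySpec(),
                  use_printed_total: bool = False) -> EnergyBreakdown:
    """Attach battery life in hours to an energy breakdown.

    ``use_printed_total`` divides by the 3-decimal printed total instead of
    the unrounded one (reproducing the published table's cells exactly).
    """
    total = (breakdown.total_J_per_s_printed if use_printed_total
             else breakdown.total_J_per_s)
    if total <= 0:
        raise ValidationError("total energy must be positive")
    hours = battery_energy(battery) / total / 3600.0
    return EnergyBreakdown(device=breakdown.device,
                           link_speed_KB_s=breakdown.link_speed_KB_s,
                           sensing_J_per_s=breakdown.sensing_J_per_s,
                           transmission_J_per_s=breakdown.transmission_J_per_s,
                           battery_hours=hours)


def efficiency_ratio(a: EnergyBreakdown, b: EnergyBreakdown,
                     displayed: bool = False) -> float:
    """Battery-life ratio of device ``a`` over device ``b``.

    ``displayed=True`` uses the one-decimal display hours (19.6 / 1.9 =
    10.3, the published "about 10 times"); the default uses unrounded
    hours.
    """
    if a.battery_hours is None or b.battery_hours is None:
        raise ValidationError("compute battery_hours first")
    if a.link_speed_KB_s != b.link_speed_KB_s:
        raise ValidationError("breakdowns must share a link speed")
    if displayed:
        return a.battery_hours_display / b.battery_hours_display
    return a.battery_hours / b.battery_hours


def data_size_ratio(a: DevicePowerSpec = SOUND_SENSOR,
                    b: DevicePowerSpec = NOISE_SENSOR) -> float:
    """How many times more data per second device ``a`` produces than
    ``b`` (66.4 / 0.9 = 73.8 for the default devices)."""
    if b.data_KB_per_s <= 0:
        raise ValidationError("reference device produces no data")
    return a.data_KB_per_s / b.data_KB_per_s


def energy_table(devices: tuple[DevicePowerSpec, ...] = (SOUND_SENSOR,
                                                         NOISE_SENSOR),
                 link_speeds: tuple[float, ...] = LINK_SPEEDS_KB_S,
                 battery: BatterySpec = BatterySpec(),
                 radio: DevicePowerSpec = WIFI_RADIO) -> list[dict]:
    """The full energy-comparison table, one row per device x link speed.

    Each row carries both unrounded values and the printed display forms
    (3-decimal joules, one-decimal floored hours).
    """
    rows = []
    for device in devices:
        for speed in link_speeds:
            bd = battery_hours(total_energy(device, speed, radio), battery,
                               use_printed_total=True)
            rows.append({
                "device": device.name,
                "link_speed_KB_s": speed,
                "sensing_J": device.energy_J_per_s,
                "transmission_J": bd.transmission_J_per_s,
                "transmission_J_printed": bd.transmission_J_per_s_printed,
                "total_J": bd.total_J_per_s,
                "total_J_printed": bd.total_J_per_s_printed,
                "battery_hours": bd.battery_hours,
                "battery_hours_display": bd.battery_hours_display,
            })
    return rows
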