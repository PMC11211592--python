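"""Static ISO-3166 alpha-2 country -> reporting-region table.

FAERS reporter-country fields carry two-letter ISO codes in the modern
quarters and occasionally full English names; both are accepted.  Regions
follow the five-continent grouping used for report characterisation:
Americas, Europe, Asia (incl. Middle East), Oceania, Africa.
"""

_ALPHA2 = {
    "Americas": (
        "US CA MX BR AR CL CO PE VE EC BO PY UY GY SR GF CR PA GT HN SV NI BZ "
        "CU DO HT JM TT BB BS PR GL AW CW SX KY BM AG DM GD KN LC VC AI VG MS "
        "TC MQ GP BL MF PM FK"
    ),
    "Europe": (
        "GB DE FR IT ES PT NL BE LU IE DK SE NO FI IS CH AT PL CZ SK HU RO BG "
        "GR HR SI RS BA ME MK AL EE LV LT UA BY MD RU GE AM AZ CY MT AD MC SM "
        "VA LI GI FO AX SJ XK"
    ),
    "Asia": (
        "JP CN KR KP TW HK MO IN PK BD LK NP BT MV SG MY TH VN PH ID BN KH LA "
        "MM MN KZ KG TJ TM UZ AF IR IQ IL PS JO LB SY SA AE QA KW BH OM YE TR"
    ),
    "Oceania": "AU NZ PG FJ SB VU NC PF WS TO TV KI NR PW FM MH CK NU GU MP AS",
    "Africa": (
        "ZA EG NG KE ET TZ UG GH DZ MA TN LY SD SS ER DJ SO RW BI CD CG GA GQ "
        "CM CF TD NE ML BF CI SN GM GN GW SL LR TG BJ MR EH AO ZM ZW MW MZ NA "
        "BW LS SZ MG MU SC KM CV ST RE YT"
    ),
}

_NAMES = {
    "Americas": (
        "UNITED STATES", "UNITED STATES OF AMERICA", "USA", "CANADA", "MEXICO",
        "BRAZIL", "ARGENTINA", "CHILE", "COLOMBIA", "PERU",
    ),
    "Europe": (
        "UNITED KINGDOM", "GREAT BRITAIN", "GERMANY", "FRANCE", "ITALY",
        "SPAIN", "NETHERLANDS", "SWITZERLAND", "SWEDEN", "POLAND", "RUSSIA",
        "RUSSIAN FEDERATION",
    ),
    "Asia": (
        "JAPAN", "CHINA", "SOUTH KOREA", "KOREA, REPUBLIC OF",
        "REPUBLIC OF KOREA", "INDIA", "TAIWAN", "ISRAEL", "SAUDI ARABIA",
        "THAILAND", "SINGAPORE", "TURKEY",
    ),
    "Oceania": ("AUSTRALIA", "NEW ZEALAND"),
    "Africa": ("SOUTH AFRICA", "EGYPT", "NIGERIA", "KENYA", "MOROCCO"),
}

COUNTRY_TO_REGION: dict[str, str] = {}
for _region, _codes in _ALPHA2.items():
    for _code in _codes.split():
        COUNTRY_TO_REGION[_code] = _region
for _region, _names in _NAMES.items():
    for _name in _names:
        COUNTRY_TO_REGION[_name] = _region
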