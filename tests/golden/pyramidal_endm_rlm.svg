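<?xml version="1.0" encoding="UTF-8"?>
<svg xmlns="http://www.w3.org/2000/svg" version="1.1" width="800.0000" height="800.0000" viewBox="0 0 800.0000 800.0000">
<circle cx="400.0000" cy="400.0000" r="17.4159" fill="none" stroke="#000000" stroke-width="1.0000"/>
<circle cx="384.3088" cy="392.4435" r="4.3540" fill="#0000ff" stroke="none"/>
<line x1="384.3088" y1="392.4435" x2="298.2230" y2="350.9868" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<path d="M 350.9868 298.2230 A 112.9639 112.9639 0 0 0 287.0361 400.0000" fill="none" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="350.9868" y1="298.2230" x2="300.9983" y2="194.4208" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<path d="M 349.2261 177.5451 A 228.1757 228.1757 0 0 0 257.7348 221.6051" fill="none" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="349.2261" y1="177.5451" x2="320.8827" y2="53.3646" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="257.7348" y1="221.6051" x2="190.4503" y2="137.2330" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="287.0361" y1="400.0000" x2="187.6058" y2="400.0000" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<path d="M 192.9310 352.7378 A 212.3942 212.3942 0 0 0 208.6394 492.1544" fill="none" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="192.9310" y1="352.7378" x2="129.5408" y2="338.2695" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<path d="M 150.0581 279.6343 A 277.4146 277.4146 0 0 0 122.5854 400.0000" fill="none" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="150.0581" y1="279.6343" x2="84.6954" y2="248.1573" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="122.5854" y1="400.0000" x2="33.4526" y2="400.0000" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="208.6394" y1="492.1544" x2="132.3635" y2="528.8869" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<circle cx="396.1246" cy="416.9792" r="4.3540" fill="#00ffff" stroke="none"/>
<line x1="396.1246" y1="416.9792" x2="372.4003" y2="520.9224" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<path d="M 322.6672 496.9722 A 124.0321 124.0321 0 0 0 400.0000 524.0321" fill="none" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="322.6672" y1="496.9722" x2="269.1711" y2="564.0542" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="400.0000" y1="524.0321" x2="400.0000" y2="634.6652" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<path d="M 347.7821 628.7817 A 234.6652 234.6652 0 0 0 452.2179 628.7817" fill="none" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="347.7821" y1="628.7817" x2="334.4653" y2="687.1263" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="452.2179" y1="628.7817" x2="483.6679" y2="766.5729" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<circle cx="413.6163" cy="410.8586" r="4.3540" fill="#00ffff" stroke="none"/>
<line x1="413.6163" y1="410.8586" x2="479.7633" y2="463.6091" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<path d="M 463.6091 479.7633 A 102.0211 102.0211 0 0 0 491.9178 444.2653" fill="none" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="463.6091" y1="479.7633" x2="525.8241" y2="557.7784" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="491.9178" y1="444.2653" x2="547.5842" y2="471.0728" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<circle cx="413.6163" cy="389.1414" r="4.3540" fill="#ff0000" stroke="none"/>
<line x1="413.6163" y1="389.1414" x2="470.8392" y2="343.5076" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<path d="M 488.3351 379.8381 A 90.6068 90.6068 0 0 0 439.3128 318.3661" fill="none" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="488.3351" y1="379.8381" x2="566.9691" y2="361.8904" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<path d="M 571.2630 400.0000 A 171.2630 171.2630 0 0 0 554.3026 325.6918" fill="none" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="571.2630" y1="400.0000" x2="620.7006" y2="400.0000" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="554.3026" y1="325.6918" x2="655.1413" y2="277.1304" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="439.3128" y1="318.3661" x2="478.1271" y2="237.7674" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<path d="M 512.2685 259.2198 A 180.0646 180.0646 0 0 0 440.0682 224.4500" fill="none" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="512.2685" y1="259.2198" x2="589.8015" y2="161.9964" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="440.0682" y1="224.4500" x2="462.3632" y2="126.7691" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
</svg>
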