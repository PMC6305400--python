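<?xml version="1.0" encoding="UTF-8"?>
<svg xmlns="http://www.w3.org/2000/svg" version="1.1" width="800.0000" height="800.0000" viewBox="0 0 800.0000 800.0000">
<circle cx="400.0000" cy="400.0000" r="18.0456" fill="none" stroke="#000000" stroke-width="1.0000"/>
<circle cx="390.9772" cy="384.3721" r="4.5114" fill="#00ffff" stroke="none"/>
<line x1="390.9772" y1="384.3721" x2="360.2315" y2="331.1189" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<circle cx="409.0228" cy="415.6279" r="4.5114" fill="#00ffff" stroke="none"/>
<line x1="409.0228" y1="415.6279" x2="471.9334" y2="524.5922" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<path d="M 328.0666 524.5922 A 143.8667 143.8667 0 0 0 524.5922 328.0666" fill="none" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="328.0666" y1="524.5922" x2="289.9075" y2="590.6857" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<path d="M 209.3143 510.0925 A 220.1849 220.1849 0 0 0 510.0925 590.6857" fill="none" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="209.3143" y1="510.0925" x2="134.7292" y2="553.1542" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<path d="M 93.6917 400.0000 A 306.3083 306.3083 0 0 0 246.8458 665.2708" fill="none" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="93.6917" y1="400.0000" x2="24.0000" y2="400.0000" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="246.8458" y1="665.2708" x2="228.9767" y2="696.2210" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="510.0925" y1="590.6857" x2="550.7069" y2="661.0321" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="524.5922" y1="328.0666" x2="610.8852" y2="278.2454" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<path d="M 643.5092 400.0000 A 243.5092 243.5092 0 0 0 521.7546 189.1148" fill="none" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="643.5092" y1="400.0000" x2="737.6525" y2="400.0000" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="521.7546" y1="189.1148" x2="573.4308" y2="99.6091" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
</svg>
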