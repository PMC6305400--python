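<?xml version="1.0" encoding="UTF-8"?>
<svg xmlns="http://www.w3.org/2000/svg" version="1.1" width="800.0000" height="800.0000" viewBox="0 0 800.0000 800.0000">
<circle cx="400.0000" cy="400.0000" r="34.1818" fill="none" stroke="#000000" stroke-width="1.0000"/>
<circle cx="365.8182" cy="400.0000" r="8.5455" fill="#00ffff" stroke="none"/>
<line x1="365.8182" y1="400.0000" x2="280.3636" y2="400.0000" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<circle cx="434.1818" cy="400.0000" r="8.5455" fill="#00ffff" stroke="none"/>
<line x1="434.1818" y1="400.0000" x2="519.6364" y2="400.0000" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<path d="M 496.7879 470.3205 A 119.6364 119.6364 0 0 0 470.3205 303.2121" fill="none" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="496.7879" y1="470.3205" x2="565.9220" y2="520.5494" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<path d="M 520.5494 565.9220 A 205.0909 205.0909 0 0 0 605.0909 400.0000" fill="none" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="520.5494" y1="565.9220" x2="570.7783" y2="635.0562" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<path d="M 489.7835 676.3251 A 290.5455 290.5455 0 0 0 635.0562 570.7783" fill="none" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="489.7835" y1="676.3251" x2="516.1904" y2="757.5973" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="635.0562" y1="570.7783" x2="704.1904" y2="621.0073" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="605.0909" y1="400.0000" x2="690.5455" y2="400.0000" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="470.3205" y1="303.2121" x2="520.5494" y2="234.0780" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<path d="M 565.9220 279.4506 A 205.0909 205.0909 0 0 0 463.3766 204.9470" fill="none" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="565.9220" y1="279.4506" x2="635.0562" y2="229.2217" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="463.3766" y1="204.9470" x2="489.7835" y2="123.6749" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
</svg>
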