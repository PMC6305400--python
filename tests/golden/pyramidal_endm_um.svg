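<?xml version="1.0" encoding="UTF-8"?>
<svg xmlns="http://www.w3.org/2000/svg" version="1.1" width="800.0000" height="800.0000" viewBox="0 0 800.0000 800.0000">
<circle cx="400.0000" cy="400.0000" r="34.1818" fill="none" stroke="#000000" stroke-width="1.0000"/>
<circle cx="369.2032" cy="385.1691" r="8.5455" fill="#0000ff" stroke="none"/>
<line x1="369.2032" y1="385.1691" x2="292.2114" y2="348.0917" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<path d="M 348.0917 292.2114 A 119.6364 119.6364 0 0 0 280.3636 400.0000" fill="none" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="348.0917" y1="292.2114" x2="311.0144" y2="215.2195" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<path d="M 354.3630 200.0511 A 205.0909 205.0909 0 0 0 272.1279 239.6535" fill="none" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="354.3630" y1="200.0511" x2="335.3476" y2="116.7391" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="272.1279" y1="239.6535" x2="218.8479" y2="172.8424" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="280.3636" y1="400.0000" x2="194.9091" y2="400.0000" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<path d="M 200.0511 354.3630 A 205.0909 205.0909 0 0 0 215.2195 488.9856" fill="none" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="200.0511" y1="354.3630" x2="116.7391" y2="335.3476" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<path d="M 138.2276 273.9371 A 290.5455 290.5455 0 0 0 109.4545 400.0000" fill="none" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="138.2276" y1="273.9371" x2="61.2357" y2="236.8597" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="109.4545" y1="400.0000" x2="24.0000" y2="400.0000" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="215.2195" y1="488.9856" x2="138.2276" y2="526.0629" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<circle cx="392.3938" cy="433.3248" r="8.5455" fill="#00ffff" stroke="none"/>
<line x1="392.3938" y1="433.3248" x2="373.3784" y2="516.6368" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<path d="M 325.4079 493.5355 A 119.6364 119.6364 0 0 0 400.0000 519.6364" fill="none" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="325.4079" y1="493.5355" x2="272.1279" y2="560.3465" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="400.0000" y1="519.6364" x2="400.0000" y2="605.0909" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<path d="M 354.3630 599.9489 A 205.0909 205.0909 0 0 0 445.6370 599.9489" fill="none" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="354.3630" y1="599.9489" x2="335.3476" y2="683.2609" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="445.6370" y1="599.9489" x2="464.6524" y2="683.2609" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<circle cx="426.7244" cy="421.3120" r="8.5455" fill="#00ffff" stroke="none"/>
<line x1="426.7244" y1="421.3120" x2="493.5355" y2="474.5921" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<path d="M 474.5921 493.5355 A 119.6364 119.6364 0 0 0 507.7886 451.9083" fill="none" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="474.5921" y1="493.5355" x2="527.8721" y2="560.3465" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="507.7886" y1="451.9083" x2="584.7805" y2="488.9856" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<circle cx="426.7244" cy="378.6880" r="8.5455" fill="#ff0000" stroke="none"/>
<line x1="426.7244" y1="378.6880" x2="493.5355" y2="325.4079" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<path d="M 516.6368 373.3784 A 119.6364 119.6364 0 0 0 451.9083 292.2114" fill="none" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="516.6368" y1="373.3784" x2="599.9489" y2="354.3630" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<path d="M 605.0909 400.0000 A 205.0909 205.0909 0 0 0 584.7805 311.0144" fill="none" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="605.0909" y1="400.0000" x2="690.5455" y2="400.0000" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="584.7805" y1="311.0144" x2="661.7724" y2="273.9371" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="451.9083" y1="292.2114" x2="488.9856" y2="215.2195" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<path d="M 527.8721 239.6535 A 205.0909 205.0909 0 0 0 445.6370 200.0511" fill="none" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="527.8721" y1="239.6535" x2="581.1521" y2="172.8424" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="445.6370" y1="200.0511" x2="464.6524" y2="116.7391" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
</svg>
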