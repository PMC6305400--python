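<?xml version="1.0" encoding="UTF-8"?>
<svg xmlns="http://www.w3.org/2000/svg" version="1.1" width="800.0000" height="800.0000" viewBox="0 0 800.0000 800.0000">
<circle cx="400.0000" cy="400.0000" r="18.0456" fill="none" stroke="#000000" stroke-width="1.0000"/>
<circle cx="381.9544" cy="400.0000" r="4.5114" fill="#00ffff" stroke="none"/>
<line x1="381.9544" y1="400.0000" x2="320.4629" y2="400.0000" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<circle cx="418.0456" cy="400.0000" r="4.5114" fill="#00ffff" stroke="none"/>
<line x1="418.0456" y1="400.0000" x2="543.8667" y2="400.0000" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<path d="M 516.3906 484.5627 A 143.8667 143.8667 0 0 0 484.5627 283.6094" fill="none" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="516.3906" y1="484.5627" x2="578.1334" y2="529.4215" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<path d="M 529.4215 578.1334 A 220.1849 220.1849 0 0 0 620.1849 400.0000" fill="none" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="529.4215" y1="578.1334" x2="580.0435" y2="647.8087" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<path d="M 494.6545 691.3165 A 306.3083 306.3083 0 0 0 647.8087 580.0435" fill="none" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="494.6545" y1="691.3165" x2="516.1904" y2="757.5973" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="647.8087" y1="580.0435" x2="676.7214" y2="601.0499" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="620.1849" y1="400.0000" x2="701.4139" y2="400.0000" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="484.5627" y1="283.6094" x2="543.1311" y2="202.9969" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<path d="M 597.0031 256.8689 A 243.5092 243.5092 0 0 0 475.2485 168.4090" fill="none" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="597.0031" y1="256.8689" x2="673.1666" y2="201.5328" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="475.2485" y1="168.4090" x2="507.1861" y2="70.1151" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
</svg>
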